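"""Imbalance-aware soft Dice losses over 3-class soft predictions.

Two losses are provided:

* **WDL** — weighted Dice loss.  Per class ``l`` the soft Dice is

      D_l = (2 * sum_n p_ln r_ln + eps) / (sum_n p_ln + sum_n r_ln + eps)

  and the loss is ``1 - sum_l w_l D_l`` with the class weights ``w_l``
  normalized to sum to one (uniform by default).

* **FBDL** — frequency-balancing boundary-emphasizing Dice loss.  Class
  weights are proportional to inverse class frequency in the reference
  (balancing SAT against the much sparser, spatially complex VAT), and a
  per-voxel weight

      m_n = 1 + (beta - 1) * 1[n within d voxels of a label boundary]

  multiplies every term inside the Dice sums, emphasizing errors near
  reference label boundaries.  Boundaries are the morphological gradient
  of the one-hot reference with a 6-connected structuring element.

With ``beta = 1`` and equal class frequencies FBDL reduces exactly to the
uniform-weight WDL.  Both losses live in [0, 1] and are differentiable in
the predicted probabilities (no argmax inside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SegMask
from .nn import autodiff as ad

__all__ = ["LossConfig", "weighted_dice_loss", "fbdl", "boundary_weights",
           "inverse_frequency_weights", "soft_dice_per_class",
           "training_loss"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


@dataclass
class LossConfig:
    type: str = "WDL"                      # WDL | FBDL
    class_weight_mode: str = "manual"      # manual | inverse_frequency_dataset
                                           # | inverse_frequency_batch
    class_weights: tuple[float, ...] | None = None   # normalized if given
    include_background: bool = True
    boundary_band_voxels: int = 1
    boundary_multiplier: float = 2.0
    smoothing: float = 1e-5

    def __post_init__(self):
        if self.type not in ("WDL", "FBDL"):
            raise ValueError(f"unknown loss type {self.type!r}")
        if self.boundary_multiplier < 1:
            raise ValueError("boundary_multiplier must be >= 1")
        if self.boundary_band_voxels < 1:
            raise ValueError("boundary_band_voxels must be >= 1")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("class weights must be >= 0 with positive sum")
            self.class_weights = tuple(w / w.sum())


def _as_onehot(ref, n_classes: int) -> np.ndarray:
    if isinstance(ref, SegMask):
        return ref.onehot(n_classes)
    ref = np.asarray(ref)
    if ref.shape[0] == n_classes and ref.ndim == 4:
        return ref.astype(np.float32, copy=False)
    return np.stack([(ref == l) for l in range(n_classes)]).astype(np.float32)


def _check_grids(probs, ref_onehot):
    if probs.shape != ref_onehot.shape:
        raise ValueError(
            f"probability map {probs.shape} and reference {ref_onehot.shape} "
            "are on different grids"
        )


def inverse_frequency_weights(ref_onehot: np.ndarray,
                              include_background: bool = True) -> np.ndarray:
    """w_l ∝ 1 / freq_l with a one-voxel-equivalent frequency floor, so a
    class absent from the weighting scope never divides by zero."""
    n = ref_onehot[0].size
    counts = ref_onehot.reshape(ref_onehot.shape[0], -1).sum(axis=1,
                                                             dtype=np.float64)
    freq = np.maximum(counts, 1.0) / n
    w = 1.0 / freq
    if not include_background:
        w[0] = 0.0
    return w / w.sum()


def _uniform_weights(n_classes: int, include_background: bool) -> np.ndarray:
    w = np.ones(n_classes)
    if not include_background:
        w[0] = 0.0
    return w / w.sum()


def resolve_class_weights(cfg: LossConfig, ref_onehot: np.ndarray,
                          dataset_onehot_counts: np.ndarray | None = None
                          ) -> np.ndarray:
    n_classes = ref_onehot.shape[0]
    if cfg.class_weights is not None:
        return np.asarray(cfg.class_weights, dtype=float)
    if cfg.class_weight_mode == "manual":
        return _uniform_weights(n_classes, cfg.include_background)
    if cfg.class_weight_mode == "inverse_frequency_batch":
        return inverse_frequency_weights(ref_onehot, cfg.include_background)
    if cfg.class_weight_mode == "inverse_frequency_dataset":
        if dataset_onehot_counts is None:
            return inverse_frequency_weights(ref_onehot,
                                             cfg.include_background)
        counts = np.maximum(np.asarray(dataset_onehot_counts, float), 1.0)
        w = 1.0 / (counts / counts.sum())
        if not cfg.include_background:
            w[0] = 0.0
        return w / w.sum()
    raise ValueError(f"unknown class_weight_mode {cfg.class_weight_mode!r}")


def boundary_weights(ref, band_voxels: int = 1,
                     multiplier: float = 2.0) -> np.ndarray:
    """Per-voxel weight map m_n emphasizing the reference boundary band."""
    labels = ref.labels if isinstance(ref, SegMask) else np.asarray(ref)
    if labels.ndim != 3:
        raise ValueError("boundary weights are defined on a 3D label volume")
    boundary = np.zeros(labels.shape, dtype=bool)
    for l in np.unique(labels):
        m = labels == l
        grad = ndimage.binary_dilation(m, _STRUCT6) \
            & ~ndimage.binary_erosion(m, _STRUCT6)
        boundary |= grad
    if band_voxels > 1:
        boundary = ndimage.binary_dilation(boundary, _STRUCT6,
                                           iterations=band_voxels - 1)
    return (1.0 + (multiplier - 1.0) * boundary).astype(np.float32)


def soft_dice_per_class(probs: np.ndarray, ref_onehot: np.ndarray,
                        voxel_weights=1.0, eps: float = 1e-5) -> np.ndarray:
    """Voxel-weighted soft Dice per class; sums run over all voxels."""
    c = probs.shape[0]
    p = probs.reshape(c, -1)
    r = ref_onehot.reshape(c, -1)
    if np.ndim(voxel_weights):
        m = np.asarray(voxel_weights).reshape(1, -1)
    else:
        m = np.full((1, 1), float(voxel_weights))
    num = 2.0 * (m * p * r).sum(axis=1) + eps
    den = (m * p).sum(axis=1) + (m * r).sum(axis=1) + eps
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den  # 0/0 only for classes later masked out by w=0


def weighted_dice_loss(probs: np.ndarray, ref, cfg: LossConfig | None = None
                       ) -> float:
    """WDL: 1 - sum_l w_l D_l on a (C, X, Y, Z) probability map."""
    cfg = cfg or LossConfig(type="WDL")
    probs = np.asarray(probs)
    ref_onehot = _as_onehot(ref, probs.shape[0])
    _check_grids(probs, ref_onehot)
    w = resolve_class_weights(cfg, ref_onehot)
    if w.sum() <= 0:
        raise ValueError("class weights sum to zero")
    dice = soft_dice_per_class(probs, ref_onehot, 1.0, cfg.smoothing)
    active = w > 0
    return float(1.0 - (w[active] * dice[active]).sum())


def fbdl(probs: np.ndarray, ref, cfg: LossConfig | None = None,
         dataset_onehot_counts: np.ndarray | None = None) -> float:
    """FBDL: inverse-frequency class weights + boundary-band voxel weights."""
    cfg = cfg or LossConfig(type="FBDL",
                            class_weight_mode="inverse_frequency_batch")
    probs = np.asarray(probs)
    ref_onehot = _as_onehot(ref, probs.shape[0])
    _check_grids(probs, ref_onehot)
    if cfg.class_weights is not None or cfg.class_weight_mode == "manual":
        w = resolve_class_weights(cfg, ref_onehot)
    else:
        w = resolve_class_weights(
            dataclass_replace_freq(cfg), ref_onehot, dataset_onehot_counts
        )
    labels = ref.labels if isinstance(ref, SegMask) else \
        np.argmax(ref_onehot, axis=0)
    m = boundary_weights(labels, cfg.boundary_band_voxels,
                         cfg.boundary_multiplier).reshape(-1)
    dice = soft_dice_per_class(probs, ref_onehot, m, cfg.smoothing)
    active = w > 0
    return float(1.0 - (w[active] * dice[active]).sum())


def dataclass_replace_freq(cfg: LossConfig) -> LossConfig:
    if cfg.class_weight_mode == "manual":
        import dataclasses
        return dataclasses.replace(
            cfg, class_weight_mode="inverse_frequency_batch"
        )
    return cfg


def training_loss(probs: ad.Tensor, ref_onehot: np.ndarray,
                  class_weights: np.ndarray,
                  voxel_weights=1.0, eps: float = 1e-5) -> ad.Tensor:
    """Autodiff-integrated weighted soft Dice for the training loop; the
    same arithmetic as the numpy losses, applied to a batched tensor."""
    return ad.weighted_soft_dice_loss(probs, ref_onehot, class_weights,
                                      voxel_weights, eps)
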