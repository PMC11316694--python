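"""Cohort splitting, input normalization, training and inference loops.

Training conventions: full-field-of-view volumes (no patching), gradients
zeroed before each batch, no data augmentation of any kind, best-epoch
selection by validation loss, and single-device determinism from one
integer seed.  Input normalization is tied to the architecture family by
default: per-channel rescaling to [0, 255] for the U-Net variants,
per-image z-scoring for the nnU-Net-style model.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MultiContrastVolume, SegMask
from .losses import (LossConfig, boundary_weights, resolve_class_weights,
                     training_loss)
from .metrics import MetricsReport, evaluate_masks, kruskal_wallis
from .nn import autodiff as ad
from .nn.models import NetworkConfig, forward_probs
from .nn.optim import Adam, SGDNesterov

log = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("op", "water", "fat")


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    input_channels: tuple[str, ...] = DEFAULT_CHANNELS
    normalization: str | None = None    # derived from arch when None
    optimizer: str = "adam"             # adam | sgd_nesterov
    learning_rate: float | None = None  # 1e-4 adam / 0.01 sgd when None
    sgd_momentum: float = 0.99
    epochs: int = 30
    batch_size: int = 2
    # optional step decay: multiply the lr by final_lr_factor for the last
    # final_lr_epochs epochs (0 = constant learning rate throughout)
    final_lr_epochs: int = 0
    final_lr_factor: float = 0.25
    # re-estimate batch-norm running statistics over the training set after
    # the best-epoch weights are restored, so single-volume inference sees
    # the same normalization the training batches did
    recalibrate_norm: bool = False
    seed: int = 0

    def resolved_normalization(self) -> str:
        if self.normalization is not None:
            return self.normalization
        return ("zscore" if self.network.arch == "nnunet_like"
                else "rescale_0_255")

    def resolved_lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.01 if self.optimizer == "sgd_nesterov" else 1e-4


# ---------------------------------------------------------------------------
# normalization

def normalize_array(x: np.ndarray, mode: str) -> np.ndarray:
    """Normalize a (C, X, Y, Z) stack per channel.

    ``rescale_0_255`` maps each channel's min -> 0 and max -> 255;
    ``zscore`` subtracts the mean and divides by the standard deviation.
    A constant channel yields all zeros in either mode (documented
    degenerate case, not an exception).
    """
    x = np.asarray(x, dtype=np.float32)
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        v = x[c]
        if mode == "rescale_0_255":
            lo, hi = float(v.min()), float(v.max())
            out[c] = 0.0 if hi == lo else (v - lo) * (255.0 / (hi - lo))
        elif mode == "zscore":
            sd = float(v.std())
            out[c] = 0.0 if sd == 0 else (v - v.mean()) / sd
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def normalize_volume(vol: MultiContrastVolume, mode: str
                     ) -> MultiContrastVolume:
    stacked = normalize_array(vol.stack(), mode)
    channels = {name: stacked[i] for i, name in enumerate(vol.channel_names)}
    return MultiContrastVolume(channels, vol.voxel_size_mm, vol.affine.copy(),
                               vol.subject_id, vol.timepoint)


# ---------------------------------------------------------------------------
# cohort splitting

@dataclass
class SplitAssignment:
    assignment: dict[str, str]              # subject_id -> split
    fractions: tuple[float, float, float]
    balance: pd.DataFrame                   # per-split covariate means
    kw_pvalues: dict[str, float]
    stratified: bool

    def apply(self, manifest: pd.DataFrame) -> pd.DataFrame:
        out = manifest.copy()
        out["split"] = out["subject_id"].map(self.assignment).fillna("none")
        return out


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def split_cohort(manifest: pd.DataFrame,
                 fractions=(0.70, 0.10, 0.20),
                 covariates=("adiposity_score", "age_like"),
                 seed: int = 0, alpha: float = 0.05,
                 max_retries: int = 20) -> SplitAssignment:
    """Stratified train/val/test assignment balanced on covariates.

    Subjects are binned by joint covariate quantiles and dealt to splits
    within bins with largest-remainder rounding; both timepoints of a
    subject inherit its split.  A balance report (per-split covariate
    means and Kruskal-Wallis p per covariate) is produced and the split
    is regenerated with a new sub-seed if any p <= alpha (bounded
    retries).  With too few subjects per bin, falls back to a simple
    random split with a logged warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    subjects = (manifest.drop_duplicates("subject_id")
                .set_index("subject_id")[list(covariates)])
    n = len(subjects)
    if n < 10:
        raise ValueError("need at least 10 subjects to split")

    n_bins = max(1, min(3, n // 12))
    stratified = n_bins > 1
    if stratified:
        bins = pd.Series(0, index=subjects.index)
        for cov in covariates:
            q = pd.qcut(subjects[cov], n_bins, labels=False,
                        duplicates="drop")
            bins = bins * n_bins + q.fillna(0).astype(int)
    else:
        log.warning("split_cohort: too few subjects for stratification; "
                    "using a simple random split")
        bins = pd.Series(0, index=subjects.index)

    targets = _largest_remainder(n, fractions)
    names = ("train", "val", "test")
    ss = np.random.SeedSequence([int(seed), 97])
    best = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(ss.spawn(1)[0])
        assignment: dict[str, str] = {}
        remaining = list(targets)
        # deal bin by bin, proportionally, then fix global totals
        for _, members in subjects.groupby(bins).groups.items():
            members = list(members)
            rng.shuffle(members)
            share = _largest_remainder(len(members),
                                       [t / n for t in targets])
            i = 0
            for split_name, k in zip(names, share):
                for m in members[i:i + k]:
                    assignment[m] = split_name
                i += k
            for m in members[i:]:
                assignment[m] = names[int(rng.integers(3))]
        # repair global totals
        counts = {s: sum(v == s for v in assignment.values()) for s in names}
        for s_over in names:
            while counts[s_over] > dict(zip(names, targets))[s_over]:
                s_under = next(s for s in names
                               if counts[s] < dict(zip(names, targets))[s])
                movable = [m for m, v in assignment.items() if v == s_over]
                pick = movable[int(rng.integers(len(movable)))]
                assignment[pick] = s_under
                counts[s_over] -= 1
                counts[s_under] += 1

        kw_p = {}
        for cov in covariates:
            groups = [subjects.loc[[m for m, v in assignment.items()
                                    if v == s], cov].to_numpy()
                      for s in names]
            if min(len(g) for g in groups) < 1 or all(
                np.ptp(np.concatenate(groups)) == 0 for _ in (0,)
            ):
                kw_p[cov] = 1.0
                continue
            try:
                _, p = kruskal_wallis(groups)
            except ValueError:
                p = 1.0
            kw_p[cov] = p
        candidate = (assignment, kw_p)
        if best is None or min(kw_p.values()) > min(best[1].values()):
            best = candidate
        if min(kw_p.values()) > alpha:
            best = candidate
            break
        log.info("split_cohort: covariate imbalance (p=%.3f) on attempt %d; "
                 "re-drawing", min(kw_p.values()), attempt)

    assignment, kw_p = best
    split_series = pd.Series(assignment, name="split")
    balance = subjects.join(split_series).groupby("split").agg(
        ["mean", "std", "count"])
    return SplitAssignment(assignment, tuple(fractions), balance, kw_p,
                           stratified)


# ---------------------------------------------------------------------------
# samples

@dataclass
class Sample:
    """One training/evaluation example, fully prepared in memory."""

    x: np.ndarray            # (C, X, Y, Z), normalized
    ref_onehot: np.ndarray   # (n_classes, X, Y, Z)
    labels: np.ndarray       # (X, Y, Z)
    subject_id: str
    timepoint: int
    boundary_w: np.ndarray | None = None   # (X, Y, Z) voxel weights


def make_sample(vol: MultiContrastVolume, mask: SegMask,
                config: TrainConfig) -> Sample:
    missing = [c for c in config.input_channels if c not in vol.channels]
    if missing:
        raise ValueError(f"volume lacks required channels {missing}")
    x = normalize_array(vol.stack(config.input_channels),
                        config.resolved_normalization())
    ref = mask.onehot(config.network.n_classes)
    sample = Sample(x, ref, mask.labels, vol.subject_id, vol.timepoint)
    if config.loss.type == "FBDL":
        sample.boundary_w = boundary_weights(
            mask.labels, config.loss.boundary_band_voxels,
            config.loss.boundary_multiplier)
    return sample


def _dataset_class_counts(samples) -> np.ndarray:
    counts = None
    for s in samples:
        c = s.ref_onehot.reshape(s.ref_onehot.shape[0], -1).sum(axis=1)
        counts = c if counts is None else counts + c
    return counts


def _make_optimizer(model, config: TrainConfig):
    if config.optimizer == "adam":
        return Adam(model.parameters(), lr=config.resolved_lr())
    if config.optimizer == "sgd_nesterov":
        return SGDNesterov(model.parameters(), lr=config.resolved_lr(),
                           momentum=config.sgd_momentum)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def _batch_loss(model, batch, class_w, eps, train: bool):
    xb = np.stack([s.x for s in batch])
    rb = np.stack([s.ref_onehot for s in batch])
    if batch[0].boundary_w is not None:
        mb = np.stack([s.boundary_w for s in batch])[:, None]
    else:
        mb = 1.0
    probs = model(ad.Tensor(xb, requires_grad=False))
    loss = training_loss(probs, rb, class_w, mb, eps)
    return loss


def train(model, train_samples, val_samples, config: TrainConfig):
    """Epoch loop with per-batch gradient reset and best-on-validation
    checkpointing; returns ``(model, history)`` with the model carrying
    the weights of the epoch with minimum validation loss."""
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be non-empty")
    class_w = resolve_class_weights(
        config.loss, train_samples[0].ref_onehot,
        _dataset_class_counts(train_samples)
        if config.loss.class_weight_mode == "inverse_frequency_dataset"
        else None,
    )
    log.info("resolved class weights: %s; loss=%s beta=%s d=%s eps=%s",
             np.round(class_w, 4), config.loss.type,
             config.loss.boundary_multiplier,
             config.loss.boundary_band_voxels, config.loss.smoothing)
    opt = _make_optimizer(model, config)
    eps = config.loss.smoothing
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)
    base_lr = config.resolved_lr()
    for epoch in range(config.epochs):
        if (config.final_lr_epochs
                and epoch >= config.epochs - config.final_lr_epochs):
            opt.lr = base_lr * config.final_lr_factor
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919, epoch]))
        order = rng.permutation(len(train_samples))
        model.train()
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i]
                     for i in order[start:start + config.batch_size]]
            opt.zero_grad()  # gradients zeroed before each batch
            loss = _batch_loss(model, batch, class_w, eps, train=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        with ad.no_grad():
            val_losses = [
                float(_batch_loss(model, [s], class_w, eps, False).data)
                for s in val_samples
            ]
        tr, vl = float(np.mean(losses)), float(np.mean(val_losses))
        if not np.isfinite(vl):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, copy.deepcopy(model.state_dict()), epoch)
        log.info("epoch %d train %.4f val %.4f", epoch, tr, vl)
    history["best_epoch"] = best[2]
    if best[1] is not None:
        model.load_state_dict(best[1])
    if config.recalibrate_norm:
        recalibrate_norm_stats(model, train_samples, config.batch_size)
    model.eval()
    return model, history


def recalibrate_norm_stats(model, samples, batch_size: int):
    """Re-estimate normalization running statistics with an equal-weight
    pass over the training samples (cumulative moving average)."""
    from .nn.layers import _Norm

    norms = [m for m in model.modules()
             if isinstance(m, _Norm) and m.track_running]
    for m in norms:
        m.running_mean[...] = 0.0
        m.running_var[...] = 1.0
    model.train()
    with ad.no_grad():
        for i, start in enumerate(range(0, len(samples), batch_size)):
            for m in norms:
                m.momentum = 1.0 / (i + 1)   # turns EMA into a plain average
            xb = np.stack([s.x for s in samples[start:start + batch_size]])
            model(ad.Tensor(xb))
    for m in norms:
        m.momentum = 0.1
    model.eval()


# ---------------------------------------------------------------------------
# evaluation

def predict_mask(model, vol: MultiContrastVolume,
                 config: TrainConfig | None = None) -> SegMask:
    """Argmax segmentation from a full-FOV single forward pass."""
    config = config or TrainConfig(network=model.config)
    x = normalize_array(vol.stack(config.input_channels),
                        config.resolved_normalization())
    probs = forward_probs(model, x)
    return SegMask(np.argmax(probs, axis=0).astype(np.uint8),
                   vol.voxel_size_mm, vol.affine.copy(), vol.subject_id,
                   vol.timepoint)


def evaluate_cohort(model, entries, train_subject_ids=(),
                    timepoint: int | None = None,
                    config: TrainConfig | None = None,
                    predictor=None) -> MetricsReport:
    """Per-subject prediction and metrics over an evaluation set.

    ``entries`` is an iterable of ``(MultiContrastVolume, SegMask)``
    pairs.  A test subject appearing in ``train_subject_ids`` is split
    leakage and a hard error.  Evaluation performs no weight update; for
    ``timepoint=2`` this is the longitudinal generalization protocol
    (the timepoint-1-trained model, no further training).
    """
    train_ids = set(train_subject_ids)
    predictor = predictor or (lambda vol: predict_mask(model, vol, config))
    rows = []
    for vol, ref in entries:
        if vol.subject_id in train_ids:
            raise RuntimeError(
                f"split leakage: subject {vol.subject_id} present in the "
                "training manifest")
        if timepoint is not None and vol.timepoint != timepoint:
            continue
        with ad.no_grad():
            pred = predictor(vol)
        rows.append(evaluate_masks(pred, ref))
    if not rows:
        raise ValueError("no entries matched the requested timepoint")
    return MetricsReport(pd.DataFrame(rows))
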