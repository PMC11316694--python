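"""Core containers shared across the package.

Label convention for all masks: 0 = background, 1 = subcutaneous adipose
tissue (SAT), 2 = visceral adipose tissue (VAT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BACKGROUND, SAT, VAT = 0, 1, 2
LABELS = (BACKGROUND, SAT, VAT)
CHANNEL_ORDER = ("op", "water", "fat")  # opposed-phase, water, fat


def ras_affine(voxel_size_mm) -> np.ndarray:
    """RAS+ affine with the grid centre at the world origin is not required;
    a plain diagonal scaling keeps orientation explicit and positive."""
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = voxel_size_mm
    return a


@dataclass
class MultiContrastVolume:
    """Co-registered Dixon channels on one voxel grid.

    ``channels`` maps channel name -> 3D array; insertion order is the
    channel order and is fixed at construction.
    """

    channels: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = None
    subject_id: str = "unknown"
    timepoint: int = 1

    def __post_init__(self):
        shapes = {k: v.shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes disagree: {shapes}")
        if self.affine is None:
            self.affine = ras_affine(self.voxel_size_mm)
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def stack(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        """(C, X, Y, Z) array in the given (or recorded) channel order."""
        order = order or self.channel_names
        return np.stack([self.channels[c] for c in order], axis=0)


@dataclass
class SegMask:
    """3-label segmentation volume on the same grid as its paired images."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = None
    subject_id: str = "unknown"
    timepoint: int = 1

    def __post_init__(self):
        if self.affine is None:
            self.affine = ras_affine(self.voxel_size_mm)
        bad = np.setdiff1d(np.unique(self.labels), LABELS)
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2}}: {bad.tolist()}")

    @property
    def shape(self):
        return self.labels.shape

    def onehot(self, n_classes: int = 3) -> np.ndarray:
        """(n_classes, X, Y, Z) one-hot indicator channels r_ln."""
        return np.stack([(self.labels == l) for l in range(n_classes)]).astype(
            np.float32
        )

    def class_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class GroundTruthRecord:
    """Exact phantom ground truth used by volume-agreement checks."""

    sat_volume_mL: float
    vat_volume_mL: float
    analytic_sat_volume_mL: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sat_volume_mL < 0 or self.vat_volume_mL < 0:
            raise ValueError("volumes must be non-negative")
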