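"""NIfTI readers/writers, cohort manifests, and slice-stack selection.

Internal orientation convention: RAS+, superior = increasing slice index.
Files whose affine says otherwise are reoriented to RAS+ on read, so the
landmark-based stack selection can assume one convention.  All slice
ranges are 0-based and inclusive-inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import MultiContrastVolume, SegMask

MANIFEST_NAME = "manifest.csv"
SPLITS = ("train", "val", "test", "none")


# ---------------------------------------------------------------------------
# volumes

def _load_canonical(path):
    img = nib.as_closest_canonical(nib.load(str(path)))
    return np.asarray(img.dataobj), img.affine


def _voxel_size(affine) -> tuple[float, float, float]:
    return tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


def read_volume(paths: dict[str, str], subject_id: str = "unknown",
                timepoint: int = 1) -> MultiContrastVolume:
    """Read co-registered channels; ``paths`` maps channel name -> file.

    Channels must share shape and affine; a mismatch is a hard error
    naming the offending file.
    """
    channels, affines = {}, {}
    for name, path in paths.items():
        data, affine = _load_canonical(path)
        channels[name] = np.asarray(data, dtype=np.float32)
        affines[name] = (affine, str(path))
    names = list(channels)
    ref_name = names[0]
    ref_shape = channels[ref_name].shape
    ref_affine = affines[ref_name][0]
    for name in names[1:]:
        if channels[name].shape != ref_shape:
            raise ValueError(
                f"channel shape mismatch: {affines[name][1]} has "
                f"{channels[name].shape}, {affines[ref_name][1]} has {ref_shape}"
            )
        if not np.allclose(affines[name][0], ref_affine, atol=1e-4):
            raise ValueError(
                f"channel affine mismatch in {affines[name][1]} "
                f"(reference {affines[ref_name][1]})"
            )
    return MultiContrastVolume(channels, _voxel_size(ref_affine), ref_affine,
                               subject_id, timepoint)


def read_mask(path, subject_id: str = "unknown", timepoint: int = 1) -> SegMask:
    data, affine = _load_canonical(path)
    return SegMask(np.asarray(np.rint(data), dtype=np.uint8),
                   _voxel_size(affine), affine, subject_id, timepoint)


def write_volume(vol: MultiContrastVolume, out_dir) -> dict[str, Path]:
    """One NIfTI per channel, suffixes ``_op`` / ``_water`` / ``_fat`` (and
    ``_ip`` when present)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{vol.subject_id}_tp{vol.timepoint}"
    paths = {}
    for name, arr in vol.channels.items():
        p = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), vol.affine), p)
        paths[name] = p
    return paths


def write_mask(mask: SegMask, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / f"{mask.subject_id}_tp{mask.timepoint}_mask.nii.gz"
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), mask.affine), p)
    return p


def write_subject(vol: MultiContrastVolume, mask: SegMask, out_dir):
    paths = write_volume(vol, out_dir)
    paths["mask"] = write_mask(mask, out_dir)
    return paths


# ---------------------------------------------------------------------------
# manifests

def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, timepoint) rows: "
            f"{df.loc[dup, 'subject_id'].tolist()}"
        )
    if "split" in df.columns:
        bad = set(df["split"].unique()) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")
        # both timepoints of a subject must carry the same split
        per_subject = df.groupby("subject_id")["split"].nunique()
        offenders = per_subject[per_subject > 1]
        if len(offenders):
            raise ValueError(
                "split differs across timepoints for subjects: "
                f"{offenders.index.tolist()}"
            )
    return df


def write_manifest(df: pd.DataFrame, out_dir, name: str = MANIFEST_NAME) -> Path:
    validate_manifest(df)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / name
    df.to_csv(p, index=False)
    return p


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "split" in df.columns:
        df["split"] = df["split"].fillna("none")
    return validate_manifest(df)


# ---------------------------------------------------------------------------
# landmark-based analysis stack

@dataclass
class AnalysisStack:
    """Inclusive slice range selected from a taller acquisition."""

    i_start: int
    i_end: int
    slice_thickness_mm: float

    @property
    def n_slices(self) -> int:
        return self.i_end - self.i_start + 1

    @property
    def s_i_extent_mm(self) -> float:
        return self.n_slices * self.slice_thickness_mm


def select_analysis_stack(n_total_slices: int, landmark_index: int,
                          n_superior: int = 50,
                          slice_thickness_mm: float = 5.0) -> AnalysisStack:
    """Landmark slice plus ``n_superior`` slices in the superior direction.

    Superior = increasing slice index (RAS+). The landmark slice is counted
    within the stack, so the default yields 51 slices.
    """
    if not 0 <= landmark_index < n_total_slices:
        raise ValueError(
            f"landmark index {landmark_index} outside [0, {n_total_slices - 1}]"
        )
    i_end = landmark_index + n_superior
    if i_end >= n_total_slices:
        available = n_total_slices - 1 - landmark_index
        raise ValueError(
            f"need {n_superior} superior slices above the landmark but only "
            f"{available} are available (short by {n_superior - available})"
        )
    return AnalysisStack(landmark_index, i_end, slice_thickness_mm)
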