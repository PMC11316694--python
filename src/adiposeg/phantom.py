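"""Synthetic two-point-Dixon abdominal phantom generator.

Builds axial torso stacks with a subcutaneous fat ring (SAT), spatially
complex scattered visceral fat (VAT) inside the abdominal cavity,
water-dominant organs, and fat-bright non-VAT confounders (a vertebral
body / bone-marrow cylinder, optional bowel fat specks) that carry the
same fat intensity as adipose tissue — so no intensity threshold can
separate them and a segmentation model must learn spatial context, the
same reason vertebral marrow must be removed manually in real Dixon
annotation workflows.

Signal model per voxel (magnitude images): with ``f`` the fat content
signal and ``w`` the water content signal,

    F     = f + noise,     W     = w + noise,
    TE_IP = w + f + noise, TE_OP = |w - f| + noise,

independent additive Gaussian noise per channel, clipped at zero (a
Rician approximation; true Rician sampling via ``rician=True``).

Determinism contract: an identical ``(spec, seed)`` pair produces
bit-identical channels, masks and ground truth.  Longitudinal pairs share
all anatomical draws (blob placement, thickness phase, roughness field)
and differ only in the scale parameters and acquisition noise, so the
two timepoints depict the same subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (BACKGROUND, SAT, VAT, GroundTruthRecord,
                   MultiContrastVolume, SegMask, ras_affine)

__all__ = [
    "PhantomSpec", "CovariateSampler", "generate_subject",
    "generate_longitudinal_pair", "generate_cohort",
]


@dataclass
class PhantomSpec:
    """All parameters of the synthetic torso generator.

    Defaults reproduce the acquisition geometry this package targets:
    a 192x192 axial matrix at 2.08 mm in-plane over a 400 mm FOV, 51
    analyzed slices of 5 mm.
    """

    matrix_size: tuple[int, int, int] = (192, 192, 51)
    voxel_size_mm: tuple[float, float, float] = (2.08, 2.08, 5.0)
    torso_axes_mm: tuple[float, float] = (150.0, 110.0)
    torso_taper: float = 0.05          # fractional shrink of the end slices
    sat_thickness_mm: float = 25.0     # mean ring thickness
    sat_thickness_mod: float = 0.2     # angular modulation amplitude (frac)
    vat_fill_fraction: float = 0.25    # target VAT fraction of cavity voxels
    n_vat_blobs: int = 6
    vat_roughness: float = 0.35        # noise-field weight in the blob score
    confounders: tuple[str, ...] = ("vertebra",)   # subset of {vertebra, bowel}
    vertebra_radius_mm: float = 16.0
    n_bowel_specks: int = 3
    adiposity_score: float = 0.0       # standardized BMI surrogate
    sat_adiposity_coeff: float = 0.15  # per unit adiposity_score
    vat_adiposity_coeff: float = 0.25
    age_like: float = 50.0             # no geometric effect; for stratification
    fat_signal: float = 1000.0
    water_signal: float = 600.0
    noise_sigma: float = 30.0
    rician: bool = False
    include_in_phase: bool = False
    subject_id: str = "phantom"
    seed: int = 0

    def effective_scales(self, d_sat: float = 0.0, d_vat: float = 0.0):
        t = self.sat_thickness_mm * (
            1.0 + self.sat_adiposity_coeff * self.adiposity_score
        ) * (1.0 + d_sat)
        fill = self.vat_fill_fraction * (
            1.0 + self.vat_adiposity_coeff * self.adiposity_score
        ) * (1.0 + d_vat)
        return t, float(np.clip(fill, 0.0, 0.95))

    def validate(self):
        nx, ny, nz = self.matrix_size
        if min(nx, ny, nz) < 8:
            raise ValueError("matrix_size must be at least 8 voxels per axis")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.vat_fill_fraction <= 1.0:
            raise ValueError("vat_fill_fraction must be in [0, 1]")
        t_eff, _ = self.effective_scales()
        t_min = t_eff * (1.0 - self.sat_thickness_mod)
        if t_min < max(self.voxel_size_mm[:2]):
            raise ValueError(
                f"SAT ring thickness {t_min:.2f} mm is below one in-plane "
                "voxel and would alias away"
            )
        dx, dy = self.voxel_size_mm[:2]
        half_fov = (nx * dx / 2.0, ny * dy / 2.0)
        ax, ay = self.torso_axes_mm
        if ax + 2 * dx > half_fov[0] or ay + 2 * dy > half_fov[1]:
            raise ValueError(
                "torso ellipse must fit inside the FOV with a 2-voxel margin"
            )
        unknown = set(self.confounders) - {"vertebra", "bowel"}
        if unknown:
            raise ValueError(f"unknown confounders: {sorted(unknown)}")


@dataclass
class CovariateSampler:
    """Cohort-level distributions for per-subject covariates and the
    longitudinal fractional changes in SAT thickness / VAT fill."""

    adiposity_mean: float = 0.0
    adiposity_sd: float = 1.0
    age_mean: float = 50.4
    age_sd: float = 14.0
    delta_sat_mean: float = 0.0
    delta_sat_sd: float = 0.05
    delta_vat_mean: float = 0.0
    delta_vat_sd: float = 0.10


@dataclass
class _Anatomy:
    """Every random draw that defines subject anatomy, made once so that
    both timepoints of a longitudinal pair share it exactly."""

    thickness_phase: float
    blob_frac_radius: np.ndarray    # (k,) radial position, fraction of cavity
    blob_angle: np.ndarray          # (k,)
    blob_frac_z: np.ndarray         # (k,)
    blob_semiaxes_mm: np.ndarray    # (k, 3)
    roughness: np.ndarray           # standardized smooth field, full grid
    bowel_frac: np.ndarray          # (n, 3) fractional placement
    bowel_radius_mm: np.ndarray     # (n,)


def _draw_anatomy(spec: PhantomSpec, rng: np.random.Generator) -> _Anatomy:
    k = spec.n_vat_blobs
    white = rng.standard_normal(spec.matrix_size)
    sigma_vox = tuple(8.0 / v for v in spec.voxel_size_mm)  # ~8 mm texture
    rough = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = rough.std()
    if sd > 0:
        rough = (rough - rough.mean()) / sd
    return _Anatomy(
        thickness_phase=float(rng.uniform(0, 2 * np.pi)),
        blob_frac_radius=rng.uniform(0.0, 0.75, size=k),
        blob_angle=rng.uniform(0, 2 * np.pi, size=k),
        blob_frac_z=rng.uniform(0.15, 0.85, size=k),
        blob_semiaxes_mm=np.column_stack(
            [rng.uniform(12, 40, size=k), rng.uniform(12, 40, size=k),
             rng.uniform(15, 45, size=k)]
        ),
        roughness=rough.astype(np.float32),
        bowel_frac=rng.uniform([-0.6, -0.6, 0.1], [0.6, 0.6, 0.9],
                               size=(spec.n_bowel_specks, 3)),
        bowel_radius_mm=rng.uniform(8, 14, size=spec.n_bowel_specks),
    )


def _grid_mm(spec: PhantomSpec):
    nx, ny, nz = spec.matrix_size
    dx, dy, dz = spec.voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    return x[:, None], y[None, :], nz, dz


def _slice_axes(spec: PhantomSpec, iz: int, nz: int):
    ax, ay = spec.torso_axes_mm
    if nz > 1:
        rel = 2.0 * iz / (nz - 1) - 1.0
        s = 1.0 - spec.torso_taper * rel * rel
    else:
        s = 1.0
    return ax * s, ay * s


def _build_masks(spec: PhantomSpec, anat: _Anatomy, t_eff: float,
                 fill_eff: float):
    """Label volume plus the analytic (continuous-geometry) SAT volume."""
    nx, ny, nz = spec.matrix_size
    x, y, _, dz = _grid_mm(spec)
    theta = np.arctan2(y, x)
    labels = np.zeros(spec.matrix_size, dtype=np.uint8)
    cavity = np.zeros(spec.matrix_size, dtype=bool)
    torso = np.zeros(spec.matrix_size, dtype=bool)
    confounder = np.zeros(spec.matrix_size, dtype=bool)
    analytic_area = 0.0  # running sum of ring cross-section area, mm^2

    for iz in range(nz):
        a, b = _slice_axes(spec, iz, nz)
        t = t_eff * (1.0 + spec.sat_thickness_mod
                     * np.sin(2.0 * theta + anat.thickness_phase))
        t = np.minimum(t, 0.9 * min(a, b))
        torso_z = (x / a) ** 2 + (y / b) ** 2 <= 1.0
        cavity_z = (x / (a - t)) ** 2 + (y / (b - t)) ** 2 <= 1.0
        labels[:, :, iz][torso_z & ~cavity_z] = SAT
        torso[:, :, iz] = torso_z
        cavity[:, :, iz] = cavity_z
        t_bar = min(t_eff, 0.9 * min(a, b))
        analytic_area += np.pi * (a * b - (a - t_bar) * (b - t_bar))

        if "vertebra" in spec.confounders:
            b_in = b - t_bar
            yc = -0.55 * b_in
            disk = x ** 2 + (y - yc) ** 2 <= spec.vertebra_radius_mm ** 2
            confounder[:, :, iz] |= disk & cavity_z

    if "bowel" in spec.confounders:
        zc_mm = (np.arange(nz) - (nz - 1) / 2.0) * dz
        for frac, r in zip(anat.bowel_frac, anat.bowel_radius_mm):
            a, b = spec.torso_axes_mm
            cx, cy = frac[0] * (a - t_eff), frac[1] * (b - t_eff)
            cz = (frac[2] - 0.5) * nz * dz
            d2 = ((x - cx) ** 2 + (y - cy) ** 2)[:, :, None] \
                + (zc_mm[None, None, :] - cz) ** 2
            confounder |= (d2 <= r ** 2) & cavity

    eligible = cavity & ~confounder
    n_elig = int(eligible.sum())
    if fill_eff > 0.0 and n_elig > 0:
        score = _blob_score(spec, anat, t_eff)
        n_target = int(round(fill_eff * n_elig))
        flat = score[eligible]
        order = np.argsort(-flat, kind="stable")[:n_target]
        sel = np.zeros(n_elig, dtype=bool)
        sel[order] = True
        vat = np.zeros(spec.matrix_size, dtype=bool)
        vat[eligible] = sel
        labels[vat] = VAT

    analytic_sat_mL = analytic_area * dz / 1000.0
    return labels, cavity, torso, confounder, analytic_sat_mL


def _blob_score(spec: PhantomSpec, anat: _Anatomy, t_eff: float):
    """Blob proximity + roughness score; highest-scoring cavity voxels
    become VAT, giving an exact fill-fraction target."""
    nx, ny, nz = spec.matrix_size
    x, y, _, dz = _grid_mm(spec)
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    ax, ay = spec.torso_axes_mm
    score = np.full(spec.matrix_size, -np.inf, dtype=np.float32)
    for u, ang, fz, semi in zip(anat.blob_frac_radius, anat.blob_angle,
                                anat.blob_frac_z, anat.blob_semiaxes_mm):
        cx = u * (ax - t_eff) * np.cos(ang)
        cy = u * (ay - t_eff) * np.sin(ang)
        cz = (fz - 0.5) * nz * dz
        q = ((x - cx) / semi[0]) ** 2 + ((y - cy) / semi[1]) ** 2
        q = q[:, :, None] + ((z[None, None, :] - cz) / semi[2]) ** 2
        np.maximum(score, 1.0 - q, out=score)
    return score + spec.vat_roughness * anat.roughness


def _render_channels(spec: PhantomSpec, labels, confounder, torso,
                     rng: np.random.Generator):
    adipose = (labels == SAT) | (labels == VAT) | confounder
    lean = (labels == BACKGROUND) & ~confounder & torso
    f = np.where(adipose, spec.fat_signal, 0.0)
    w = np.where(lean, spec.water_signal, 0.0)
    ideal = {"op": np.abs(w - f), "water": w, "fat": f}
    if spec.include_in_phase:
        ideal["ip"] = w + f
    out = {}
    for name, sig in ideal.items():
        if spec.noise_sigma > 0:
            n1 = rng.standard_normal(sig.shape) * spec.noise_sigma
            if spec.rician:
                n2 = rng.standard_normal(sig.shape) * spec.noise_sigma
                arr = np.sqrt((sig + n1) ** 2 + n2 ** 2)
            else:
                arr = np.clip(sig + n1, 0.0, None)
        else:
            arr = sig
        out[name] = arr.astype(np.float32)
    return out


def _voxel_mL(spec: PhantomSpec) -> float:
    dx, dy, dz = spec.voxel_size_mm
    return dx * dy * dz / 1000.0


def _generate(spec: PhantomSpec, seed: int, timepoint: int,
              d_sat: float, d_vat: float, noise_stream: int):
    spec.validate()
    t_eff, fill_eff = spec.effective_scales(d_sat, d_vat)
    t_min = t_eff * (1.0 - spec.sat_thickness_mod)
    if t_min < max(spec.voxel_size_mm[:2]):
        raise ValueError(
            f"scaled SAT ring thickness {t_min:.2f} mm is below one voxel"
        )
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1315])
    anat_ss, *noise_ss = ss.spawn(3)
    anat = _draw_anatomy(spec, np.random.default_rng(anat_ss))
    labels, _, torso, confounder, analytic_sat = _build_masks(
        spec, anat, t_eff, fill_eff
    )
    channels = _render_channels(
        spec, labels, confounder, torso,
        np.random.default_rng(noise_ss[noise_stream])
    )
    affine = ras_affine(spec.voxel_size_mm)
    vol = MultiContrastVolume(channels, spec.voxel_size_mm, affine.copy(),
                              spec.subject_id, timepoint)
    mask = SegMask(labels, spec.voxel_size_mm, affine.copy(),
                   spec.subject_id, timepoint)
    vx = _voxel_mL(spec)
    truth = GroundTruthRecord(
        sat_volume_mL=float((labels == SAT).sum() * vx),
        vat_volume_mL=float((labels == VAT).sum() * vx),
        analytic_sat_volume_mL=float(analytic_sat),
        covariates={"adiposity_score": spec.adiposity_score,
                    "age_like": spec.age_like,
                    "timepoint": timepoint},
    )
    return vol, mask, truth


def generate_subject(spec: PhantomSpec, seed: int | None = None):
    """Generate one subject at timepoint 1.

    Returns ``(MultiContrastVolume, SegMask, GroundTruthRecord)``.
    """
    seed = spec.seed if seed is None else seed
    return _generate(spec, seed, timepoint=1, d_sat=0.0, d_vat=0.0,
                     noise_stream=0)


def generate_longitudinal_pair(spec: PhantomSpec,
                               delta: tuple[float, float] = (0.0, 0.0),
                               seed: int | None = None):
    """Generate the same subject at two timepoints.

    ``delta = (d_sat_frac, d_vat_frac)`` scales the SAT ring thickness and
    the VAT fill fraction at timepoint 2 by ``(1 + d)``.  Anatomy draws are
    shared; acquisition noise is independent between timepoints.
    """
    d_sat, d_vat = delta
    if not (-0.9 < d_sat < 0.9 and -0.9 < d_vat < 0.9):
        raise ValueError("delta fractions must lie in (-0.9, 0.9)")
    seed = spec.seed if seed is None else seed
    tp1 = _generate(spec, seed, 1, 0.0, 0.0, noise_stream=0)
    tp2 = _generate(spec, seed, 2, d_sat, d_vat, noise_stream=1)
    return tp1, tp2


def generate_cohort(n: int, sampler: CovariateSampler | None = None,
                    seed: int = 0, out_dir=None,
                    base_spec: PhantomSpec | None = None):
    """Sample ``n`` subjects (two timepoints each) and return a manifest.

    If ``out_dir`` is given, channel and mask volumes are written as NIfTI
    through :mod:`adiposeg.io` and the manifest records their paths;
    otherwise path columns are empty (covariates and true volumes are
    still recorded, which is all split/stratification work needs).
    """
    import pandas as pd

    if n < 1:
        raise ValueError("cohort size must be at least 1")
    sampler = sampler or CovariateSampler()
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2718]))
    rows = []
    for i in range(n):
        adiposity = float(np.clip(
            rng.normal(sampler.adiposity_mean, sampler.adiposity_sd),
            -2.5, 2.5))
        age = float(rng.normal(sampler.age_mean, sampler.age_sd))
        d_sat = float(np.clip(
            rng.normal(sampler.delta_sat_mean, sampler.delta_sat_sd),
            -0.5, 0.5))
        d_vat = float(np.clip(
            rng.normal(sampler.delta_vat_mean, sampler.delta_vat_sd),
            -0.5, 0.5))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = dataclasses.replace(
            base_spec, adiposity_score=adiposity, age_like=age,
            subject_id=f"S{i:03d}", seed=sub_seed,
        )
        pair = generate_longitudinal_pair(spec, (d_sat, d_vat), sub_seed)
        for (vol, mask, truth), tp in zip(pair, (1, 2)):
            paths = {f"{c}_path": "" for c in vol.channel_names}
            paths["mask_path"] = ""
            if out_dir is not None:
                from . import io as volio
                written = volio.write_subject(vol, mask, out_dir)
                paths = {f"{c}_path": str(written[c])
                         for c in vol.channel_names}
                paths["mask_path"] = str(written["mask"])
            rows.append({
                "subject_id": spec.subject_id, "timepoint": tp, **paths,
                "adiposity_score": adiposity, "age_like": age,
                "delta_sat_frac": d_sat, "delta_vat_frac": d_vat,
                "sat_volume_mL": truth.sat_volume_mL,
                "vat_volume_mL": truth.vat_volume_mL,
                "analytic_sat_volume_mL": truth.analytic_sat_volume_mL,
                "seed": sub_seed, "split": "none",
            })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from . import io as volio
        volio.write_manifest(manifest, out_dir)
    return manifest
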