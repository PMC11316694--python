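"""Phantom generator: determinism, geometry oracles, contrast and
confounder properties, longitudinal pairs, cohort sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from adiposeg.core import BACKGROUND, SAT, VAT
from adiposeg.phantom import (CovariateSampler, PhantomSpec, generate_cohort,
                              generate_longitudinal_pair, generate_subject)

CIRCULAR = dict(torso_axes_mm=(120.0, 120.0), torso_taper=0.0,
                sat_thickness_mm=20.0, sat_thickness_mod=0.0,
                noise_sigma=0.0)


def annulus_mL(r_outer, thickness, extent_mm):
    return np.pi * (r_outer ** 2 - (r_outer - thickness) ** 2) * extent_mm / 1e3


def tapered_annulus_mL(spec, thickness):
    """Slice-wise analytic ring volume for the tapered circular torso,
    computed independently of the generator: per slice the torso radius is
    scaled by 1 - taper * rel^2 and the ring area is pi*t*(2r - t)."""
    nz = spec.matrix_size[2]
    dz = spec.voxel_size_mm[2]
    r0 = spec.torso_axes_mm[0]
    total = 0.0
    for iz in range(nz):
        rel = 2.0 * iz / (nz - 1) - 1.0
        r = r0 * (1.0 - spec.torso_taper * rel * rel)
        total += np.pi * thickness * (2 * r - thickness) * dz
    return total / 1e3


def test_same_spec_and_seed_is_bit_identical(small_spec):
    a = generate_subject(small_spec, seed=11)
    b = generate_subject(small_spec, seed=11)
    for name in a[0].channels:
        assert np.array_equal(a[0].channels[name], b[0].channels[name])
    assert np.array_equal(a[1].labels, b[1].labels)
    assert a[2].sat_volume_mL == b[2].sat_volume_mL


def test_zero_vat_fill_gives_empty_vat_class(small_spec):
    spec = dataclasses.replace(small_spec, vat_fill_fraction=0.0)
    _, mask, truth = generate_subject(spec, seed=2)
    assert (mask.labels == VAT).sum() == 0
    assert truth.vat_volume_mL == 0.0


def test_labels_are_exclusive_and_in_codomain(small_spec):
    _, mask, _ = generate_subject(small_spec, seed=3)
    assert set(np.unique(mask.labels)) <= {BACKGROUND, SAT, VAT}


def test_noise_free_contrast_properties(small_spec):
    """Fat channel dominates on adipose and confounder voxels, water on
    lean tissue, and the in-phase echo equals W + F exactly."""
    spec = dataclasses.replace(small_spec, noise_sigma=0.0,
                               include_in_phase=True)
    vol, mask, _ = generate_subject(spec, seed=4)
    F, W = vol.channels["fat"], vol.channels["water"]
    adipose_or_conf = F > 0
    assert ((mask.labels == SAT) <= adipose_or_conf).all()
    assert ((mask.labels == VAT) <= adipose_or_conf).all()
    assert (F[adipose_or_conf] > W[adipose_or_conf]).all()
    lean = W > 0
    assert lean.any() and (W[lean] > F[lean]).all()
    assert np.array_equal(vol.channels["ip"], W + F)
    op = vol.channels["op"]
    assert np.array_equal(op, np.abs(W - F))


def test_confounder_is_fat_bright_background_component(small_spec):
    """At least one connected fat-dominant component carries label 0,
    mirroring vertebral marrow that must not be counted as VAT."""
    spec = dataclasses.replace(small_spec, noise_sigma=0.0)
    vol, mask, _ = generate_subject(spec, seed=5)
    fat_bright_bg = (vol.channels["fat"] > vol.channels["water"]) \
        & (mask.labels == BACKGROUND)
    n_comp = ndimage.label(fat_bright_bg)[1]
    assert n_comp >= 1
    # confounder intensity equals adipose intensity: no threshold separates
    sat_fat = vol.channels["fat"][mask.labels == SAT]
    conf_fat = vol.channels["fat"][fat_bright_bg]
    assert conf_fat.max() == sat_fat.max()


def test_voxelized_sat_volume_matches_analytic_annulus():
    spec = PhantomSpec(**CIRCULAR)
    _, _, truth = generate_subject(spec, seed=6)
    expected = annulus_mL(120.0, 20.0, 51 * 5.0)
    assert truth.analytic_sat_volume_mL == pytest.approx(expected, rel=1e-6)
    assert truth.sat_volume_mL == pytest.approx(expected, rel=0.03)


def test_finer_grid_reduces_volume_discretization_error():
    base = dict(CIRCULAR, torso_taper=0.05)
    fine = PhantomSpec(**base)
    coarse = PhantomSpec(**base, matrix_size=(48, 48, 51),
                         voxel_size_mm=(8.32, 8.32, 5.0))
    expected = tapered_annulus_mL(fine, 20.0)
    err = {
        "fine": abs(generate_subject(fine, 7)[2].sat_volume_mL - expected),
        "coarse": abs(generate_subject(coarse, 7)[2].sat_volume_mL - expected),
    }
    assert err["fine"] < err["coarse"]


def test_invalid_specs_rejected(small_spec):
    with pytest.raises(ValueError, match="vat_fill_fraction"):
        generate_subject(dataclasses.replace(small_spec,
                                             vat_fill_fraction=1.2), 1)
    with pytest.raises(ValueError, match="thickness"):
        generate_subject(dataclasses.replace(small_spec,
                                             sat_thickness_mm=4.0), 1)
    with pytest.raises(ValueError, match="FOV"):
        generate_subject(dataclasses.replace(small_spec,
                                             torso_axes_mm=(260.0, 110.0)), 1)


class TestLongitudinalPair:
    def test_zero_delta_noise_free_is_identical(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_sigma=0.0)
        (v1, m1, t1), (v2, m2, t2) = generate_longitudinal_pair(
            spec, (0.0, 0.0), seed=8)
        assert np.array_equal(m1.labels, m2.labels)
        assert t2.sat_volume_mL - t1.sat_volume_mL == 0.0
        assert t2.vat_volume_mL - t1.vat_volume_mL == 0.0

    def test_delta_signs_propagate_to_volumes(self):
        spec = PhantomSpec(**CIRCULAR, matrix_size=(96, 96, 20),
                           voxel_size_mm=(4.16, 4.16, 5.0))
        (_, _, t1), (_, _, t2) = generate_longitudinal_pair(
            spec, (0.10, -0.20), seed=9)
        assert t2.sat_volume_mL > t1.sat_volume_mL
        assert t2.vat_volume_mL < t1.vat_volume_mL

    def test_sat_delta_matches_analytic_annulus_difference(self):
        spec = PhantomSpec(**dict(CIRCULAR, torso_taper=0.05))
        (_, _, t1), (_, _, t2) = generate_longitudinal_pair(
            spec, (0.10, 0.0), seed=10)
        expected = tapered_annulus_mL(spec, 22.0) - tapered_annulus_mL(
            spec, 20.0)
        measured = t2.sat_volume_mL - t1.sat_volume_mL
        assert measured == pytest.approx(expected, rel=0.05)

    def test_timepoint1_equals_single_subject(self, small_spec):
        (v1, m1, _), _ = generate_longitudinal_pair(small_spec, (0.1, 0.1),
                                                    seed=12)
        vs, ms, _ = generate_subject(small_spec, seed=12)
        assert np.array_equal(m1.labels, ms.labels)
        assert np.array_equal(v1.channels["fat"], vs.channels["fat"])

    def test_delta_out_of_range_rejected(self, small_spec):
        with pytest.raises(ValueError, match="delta"):
            generate_longitudinal_pair(small_spec, (0.95, 0.0), 1)


class TestCohort:
    def test_manifest_has_one_row_per_subject_timepoint(self, small_spec):
        df = generate_cohort(4, seed=1, base_spec=small_spec)
        assert len(df) == 8
        assert df.groupby("subject_id").size().eq(2).all()

    def test_different_seeds_give_different_covariates(self, small_spec):
        a = generate_cohort(5, seed=1, base_spec=small_spec)
        b = generate_cohort(5, seed=2, base_spec=small_spec)
        assert not np.allclose(a["adiposity_score"], b["adiposity_score"])

    def test_adiposity_mean_within_standard_error(self, small_spec):
        sampler = CovariateSampler(adiposity_mean=0.5, adiposity_sd=0.8)
        df = generate_cohort(50, sampler, seed=3, base_spec=small_spec)
        per_subject = df.drop_duplicates("subject_id")["adiposity_score"]
        assert abs(per_subject.mean() - 0.5) < 3 * 0.8 / np.sqrt(50)

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError, match="at least 1"):
            generate_cohort(0)
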