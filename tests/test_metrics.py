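"""Segmentation metrics vs brute-force voxel loops, ICC vs hand ANOVA,
longitudinal delta regression, and the rank-test / FDR layer."""

import numpy as np
import pandas as pd
import pytest

from adiposeg.core import SAT, VAT, SegMask
from adiposeg.metrics import (MetricsReport,
                              benjamini_hochberg, delta_volume_analysis,
                              dice3d, evaluate_masks, fp_fn_rates,
                              icc_agreement, icc_category, kruskal_wallis,
                              mask_volume, wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain python loops)

def brute_dice(pred, ref, label):
    inter = p_sum = r_sum = 0
    for idx in np.ndindex(ref.shape):
        p, r = pred[idx] == label, ref[idx] == label
        inter += p and r
        p_sum += p
        r_sum += r
    if p_sum + r_sum == 0:
        return 1.0
    return 2 * inter / (p_sum + r_sum)


def brute_fp_fn(pred, ref):
    fp_n = fp_d = fn_n = fn_d = 0
    for l in (SAT, VAT):
        for idx in np.ndindex(ref.shape):
            r, p = ref[idx] == l, pred[idx] == l
            if not r:
                fp_d += 1
                fp_n += p
            else:
                fn_d += 1
                fn_n += not p
    return 100 * fp_n / fp_d, 100 * fn_n / fn_d


def anova_iccs(a, b):
    """Two-way ANOVA mean squares -> (ICC(2,1) absolute, ICC(3,1)
    consistency); hand-computed from the standard formulas."""
    x = np.stack([a, b], axis=1).astype(float)
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand
    ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
    icc2 = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
    icc3 = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return icc2, icc3


# ---------------------------------------------------------------------------

class TestDice:
    def test_identity(self, rng):
        m = rng.integers(0, 3, (6, 6, 6))
        assert dice3d(m, m, SAT) == 1.0

    def test_hand_enumerated_toy(self):
        pred = np.array([1, 1, 0]).reshape(3, 1, 1)
        ref = np.array([1, 0, 0]).reshape(3, 1, 1)
        assert dice3d(pred, ref, SAT) == pytest.approx(2 / 3)

    def test_both_empty_class_is_one(self):
        z = np.zeros((3, 3, 3), dtype=int)
        assert dice3d(z, z, VAT) == 1.0

    def test_symmetry_and_oracle_on_random_masks(self, rng):
        for _ in range(25):
            a = rng.integers(0, 3, (5, 5, 5))
            b = rng.integers(0, 3, (5, 5, 5))
            for l in (SAT, VAT):
                assert dice3d(a, b, l) == dice3d(b, a, l)
                assert dice3d(a, b, l) == pytest.approx(brute_dice(a, b, l))

    def test_grid_mismatch(self, rng):
        with pytest.raises(ValueError, match="grid"):
            dice3d(rng.integers(0, 3, (4, 4, 4)),
                   rng.integers(0, 3, (4, 4, 5)), SAT)


class TestFpFn:
    def test_identity_is_zero_zero(self, rng):
        m = rng.integers(0, 3, (6, 6, 6))
        assert fp_fn_rates(m, m) == (0.0, 0.0)

    def test_four_voxel_worked_example(self):
        """N = 4 indicator toy: r_SAT=[1,1,0,0], r_VAT=[0,0,1,0];
        p_SAT=[1,0,0,1], p_VAT=[0,0,1,1] -> FP = 100*2/5 = 40.0,
        FN = 100*1/3.  The last voxel is positive in both prediction
        channels, so the case is fed as indicator stacks."""
        shape = (4, 1, 1)
        ref = np.zeros((3, *shape))
        ref[SAT, :2] = 1
        ref[VAT, 2] = 1
        pred = np.zeros((3, *shape))
        pred[SAT, [0, 3]] = 1
        pred[VAT, [2, 3]] = 1
        fp, fn = fp_fn_rates(pred, ref)
        assert fp == pytest.approx(40.0)
        assert fn == pytest.approx(100 / 3)

    def test_cross_class_confusion_counts_both_ways(self):
        ref = np.full((2, 1, 1), SAT)
        pred = np.full((2, 1, 1), VAT)
        fp, fn = fp_fn_rates(pred, ref)
        assert fn == 100.0          # every SAT voxel missed
        assert fp == 100.0          # every VAT-negative voxel called VAT

    def test_brute_force_equality_and_count_swap_symmetry(self, rng):
        """Exact match with the voxel-loop oracle in both argument orders;
        swapping prediction and reference swaps the FP and FN *counts*
        (the rate denominators are role-specific)."""
        for _ in range(25):
            a = rng.integers(0, 3, (5, 5, 5))
            b = rng.integers(0, 3, (5, 5, 5))
            assert fp_fn_rates(a, b) == pytest.approx(brute_fp_fn(a, b))
            assert fp_fn_rates(b, a) == pytest.approx(brute_fp_fn(b, a))
            fp_count_ab = sum(((b != l) & (a == l)).sum() for l in (SAT, VAT))
            fn_count_ba = sum(((a == l) & (b != l)).sum() for l in (SAT, VAT))
            assert fp_count_ab == fn_count_ba


class TestVolume:
    def test_acquisition_voxel_arithmetic(self):
        m = np.zeros((10, 10, 10), dtype=int)
        m.flat[:1000] = SAT
        assert mask_volume(m, SAT, (2.08, 2.08, 5.0)) == pytest.approx(
            1000 * 2.08 * 2.08 * 5.0 / 1000.0)

    def test_empty_class_is_zero(self):
        assert mask_volume(np.zeros((4, 4, 4), int), VAT, (1, 1, 1)) == 0.0

    def test_additivity_over_disjoint_subvolumes(self, rng):
        m = rng.integers(0, 3, (8, 8, 8))
        v = (1.5, 1.5, 3.0)
        assert mask_volume(m, SAT, v) == pytest.approx(
            mask_volume(m[:4], SAT, v) + mask_volume(m[4:], SAT, v))


class TestICC:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_agreement(a, a)
        assert (res.icc, res.slope, res.intercept) == (1.0, 1.0, 0.0)
        assert res.category == "excellent"

    def test_offset_series_absolute_below_consistency(self):
        """b = a + c with c >> spread: absolute-agreement ICC must fall
        strictly below consistency ICC; both match hand ANOVA sums."""
        a = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        b = a + 30.0
        abs_res = icc_agreement(a, b, "ICC2")
        con_res = icc_agreement(a, b, "ICC3")
        icc2, icc3 = anova_iccs(a, b)
        assert abs_res.icc == pytest.approx(icc2, abs=1e-9)
        assert con_res.icc == pytest.approx(icc3, abs=1e-9)
        assert abs_res.icc < con_res.icc

    def test_random_series_match_anova_oracle(self, rng):
        a = rng.normal(100, 10, 12)
        b = a + rng.normal(0, 3, 12)
        res = icc_agreement(a, b, "ICC2")
        assert res.icc == pytest.approx(anova_iccs(a, b)[0], abs=1e-9)
        assert res.icc <= 1.0

    def test_icc_equals_pearson_in_no_bias_equal_variance_limit(self, rng):
        a = rng.normal(50, 8, 2000)
        noise = rng.normal(0, 2, 2000)
        b = a + noise - noise.mean()
        r = np.corrcoef(a, b)[0, 1]
        assert icc_agreement(a, b).icc == pytest.approx(r, abs=0.01)

    def test_categories_at_printed_cutpoints(self):
        assert icc_category(0.93) == "excellent"
        assert icc_category(0.45) == "poor"
        assert icc_category(0.6) == "moderate"
        assert icc_category(0.8) == "good"

    def test_zero_variance_undefined(self):
        res = icc_agreement([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert np.isnan(res.icc) and res.category == "undefined"


def _report(subjects, tp, sat, vat, ref_sat, ref_vat):
    return MetricsReport(pd.DataFrame({
        "subject_id": subjects, "timepoint": tp,
        "dice_sat": 1.0, "dice_vat": 1.0, "fp_pct": 0.0, "fn_pct": 0.0,
        "sat_volume_mL": sat, "vat_volume_mL": vat,
        "ref_sat_volume_mL": ref_sat, "ref_vat_volume_mL": ref_vat,
    }))


class TestDeltaVolume:
    def test_perfect_predictions_give_slope_one_intercept_zero(self, rng):
        subs = [f"s{i}" for i in range(8)]
        v1 = rng.normal(3000, 300, 8)
        v2 = v1 + rng.normal(0, 150, 8)
        w1, w2 = rng.normal(1500, 200, 8), rng.normal(1500, 200, 8)
        r1 = _report(subs, 1, v1, w1, v1, w1)
        r2 = _report(subs, 2, v2, w2, v2, w2)
        out = delta_volume_analysis(r1, r2).set_index("tissue")
        for t in ("SAT", "VAT"):
            assert out.loc[t, "slope"] == pytest.approx(1.0)
            assert out.loc[t, "intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_slope_approaches_one_as_noise_vanishes(self, rng):
        subs = [f"s{i}" for i in range(40)]
        v1 = rng.normal(3000, 300, 40)
        v2 = v1 + rng.normal(0, 200, 40)
        slopes = []
        for sd in (100.0, 1.0):
            r1 = _report(subs, 1, v1 + rng.normal(0, sd, 40), v1, v1, v1)
            r2 = _report(subs, 2, v2 + rng.normal(0, sd, 40), v2, v2, v2)
            out = delta_volume_analysis(r1, r2).set_index("tissue")
            slopes.append(out.loc["SAT", "slope"])
        assert abs(slopes[1] - 1.0) < abs(slopes[0] - 1.0)
        assert slopes[1] == pytest.approx(1.0, abs=0.01)

    def test_missing_timepoint_names_subject(self, rng):
        r1 = _report(["a", "b", "c"], 1, [1, 2, 3], [1, 2, 3], [1, 2, 3],
                     [1, 2, 3])
        r2 = _report(["a", "b"], 2, [1, 2], [1, 2], [1, 2], [1, 2])
        with pytest.raises(ValueError, match="c"):
            delta_volume_analysis(r1, r2)


class TestStatsLayer:
    def test_kruskal_wallis_matches_scipy_contract(self, rng):
        g = [rng.normal(0, 1, 20), rng.normal(0, 1, 20),
             rng.normal(2, 1, 20)]
        h, p = kruskal_wallis(g)
        assert h > 0 and p < 0.01
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([g[0]])

    def test_wilcoxon_identical_pairs_gives_p_one(self):
        a = np.arange(10.0)
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_wilcoxon_detects_shift(self, rng):
        a = rng.normal(0, 1, 30)
        assert wilcoxon_signed_rank(a, a + 1.0) < 1e-4

    def test_bh_example_rejects_all_four(self):
        reject, _ = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_bh_matches_definitional_brute_force(self, rng):
        """Step-up rule applied literally: reject all i <= argmax
        {i : p(i) <= i q / m}."""
        for _ in range(50):
            m = int(rng.integers(1, 12))
            p = rng.random(m)
            reject, p_adj = benjamini_hochberg(p, q=0.05)
            order = np.argsort(p)
            ks = [i for i in range(1, m + 1)
                  if p[order[i - 1]] <= i * 0.05 / m]
            expected = np.zeros(m, bool)
            if ks:
                expected[order[:max(ks)]] = True
            np.testing.assert_array_equal(reject, expected)
            # adjusted p non-decreasing in raw-p rank
            assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_bh_larger_q_never_rejects_fewer(self, rng):
        p = rng.random(20)
        r1, _ = benjamini_hochberg(p, q=0.01)
        r2, _ = benjamini_hochberg(p, q=0.10)
        assert (r2 | ~r1).all()


def test_evaluate_masks_collects_all_fields(rng):
    labels = rng.integers(0, 3, (6, 6, 6)).astype(np.uint8)
    ref = SegMask(labels, (2.0, 2.0, 5.0), subject_id="s1", timepoint=2)
    pred = SegMask(labels.copy(), (2.0, 2.0, 5.0), subject_id="s1",
                   timepoint=2)
    row = evaluate_masks(pred, ref)
    assert row["dice_sat"] == row["dice_vat"] == 1.0
    assert row["fp_pct"] == row["fn_pct"] == 0.0
    assert row["sat_volume_mL"] == row["ref_sat_volume_mL"]
    assert (row["subject_id"], row["timepoint"]) == ("s1", 2)
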