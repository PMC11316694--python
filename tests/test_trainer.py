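"""Normalization contracts, stratified splitting, training loop
determinism and checkpoint selection, evaluation guards."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from adiposeg.core import MultiContrastVolume
from adiposeg.losses import LossConfig
from adiposeg.nn import build_network
from adiposeg.nn.models import NetworkConfig
from adiposeg.phantom import PhantomSpec, generate_subject
from adiposeg.trainer import (TrainConfig, evaluate_cohort, make_sample,
                              normalize_array, normalize_volume, predict_mask,
                              split_cohort, train)

TINY_SPEC = PhantomSpec(matrix_size=(32, 32, 8),
                        voxel_size_mm=(12.0, 12.0, 10.0))


def tiny_config(**kw):
    kw.setdefault("network", NetworkConfig(encoder_filters=(4, 8), seed=0))
    kw.setdefault("loss", LossConfig(type="WDL"))
    kw.setdefault("optimizer", "adam")
    kw.setdefault("learning_rate", 5e-3)
    kw.setdefault("batch_size", 1)
    kw.setdefault("seed", 0)
    return TrainConfig(**kw)


class TestNormalization:
    def test_rescale_hits_exact_range(self, rng):
        x = rng.random((2, 6, 6, 6)) * 37 + 4
        out = normalize_array(x, "rescale_0_255")
        for c in range(2):
            assert out[c].min() == 0.0
            assert out[c].max() == pytest.approx(255.0)

    def test_zscore_moments(self, rng):
        out = normalize_array(rng.random((2, 8, 8, 8)) * 10, "zscore")
        for c in range(2):
            assert abs(out[c].mean()) < 1e-5
            assert out[c].std() == pytest.approx(1.0, abs=1e-5)

    def test_zscore_invariant_to_affine_rescaling(self, rng):
        v = rng.random((1, 6, 6, 6)).astype(np.float64)
        a = normalize_array(v, "zscore")
        b = normalize_array(3.7 * v + 11.0, "zscore")
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_constant_volume_yields_zeros(self):
        x = np.full((1, 4, 4, 4), 7.0)
        assert (normalize_array(x, "rescale_0_255") == 0).all()
        assert (normalize_array(x, "zscore") == 0).all()

    def test_volume_wrapper_preserves_metadata(self, rng):
        vol = MultiContrastVolume(
            {"op": rng.random((4, 4, 4)), "water": rng.random((4, 4, 4)),
             "fat": rng.random((4, 4, 4))}, (2.0, 2.0, 5.0),
            subject_id="x", timepoint=2)
        out = normalize_volume(vol, "rescale_0_255")
        assert out.subject_id == "x" and out.timepoint == 2
        assert out.channel_names == vol.channel_names

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="normalization"):
            normalize_array(rng.random((1, 2, 2, 2)), "minmax")


def _manifest(n, seed=0):
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cov = {"adiposity_score": r.normal(), "age_like": r.normal(50, 14)}
        for tp in (1, 2):
            rows.append({"subject_id": f"s{i:03d}", "timepoint": tp, **cov})
    return pd.DataFrame(rows)


class TestSplit:
    def test_largest_remainder_sizes_for_ten_subjects(self):
        split = split_cohort(_manifest(10), (0.7, 0.1, 0.2), seed=1)
        counts = pd.Series(split.assignment).value_counts()
        assert (counts["train"], counts["val"], counts["test"]) == (7, 1, 2)

    def test_covariates_balanced_across_splits(self):
        split = split_cohort(_manifest(200), seed=2)
        assert min(split.kw_pvalues.values()) > 0.05

    def test_both_timepoints_inherit_subject_split(self):
        df = _manifest(20)
        out = split_cohort(df, seed=3).apply(df)
        assert out.groupby("subject_id")["split"].nunique().eq(1).all()

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_cohort(_manifest(20), (0.7, 0.2, 0.2))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_cohort(_manifest(5))


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_sample(self):
        vol, mask, _ = generate_subject(TINY_SPEC, 1)
        return vol, mask

    def test_overfits_single_phantom(self):
        """Capacity check: a base-8 U-Net memorizes one phantom, driving
        the soft Dice training loss under 0.05."""
        spec = PhantomSpec(matrix_size=(48, 48, 16),
                           voxel_size_mm=(8.0, 8.0, 10.0))
        vol, mask, _ = generate_subject(spec, 1)
        cfg = tiny_config(
            network=NetworkConfig(encoder_filters=(8, 16, 32), seed=0),
            epochs=120)
        s = make_sample(vol, mask, cfg)
        model = build_network(cfg.network)
        _, history = train(model, [s], [s], cfg)
        assert min(history["train_loss"]) < 0.05

    def test_fixed_seed_runs_are_bit_identical(self, tiny_sample):
        vol, mask = tiny_sample
        cfg = tiny_config(epochs=3)
        histories = []
        for _ in range(2):
            s = make_sample(vol, mask, cfg)
            model = build_network(cfg.network)
            _, h = train(model, [s], [s], cfg)
            histories.append(h)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_checkpoint_is_epoch_of_minimum_validation_loss(self, tiny_sample):
        vol, mask = tiny_sample
        cfg = tiny_config(epochs=8)
        s = make_sample(vol, mask, cfg)
        model = build_network(cfg.network)
        model, history = train(model, [s], [s], cfg)
        assert history["best_epoch"] == int(np.argmin(history["val_loss"]))

    def test_empty_sets_rejected(self, tiny_sample):
        vol, mask = tiny_sample
        cfg = tiny_config(epochs=1)
        s = make_sample(vol, mask, cfg)
        with pytest.raises(ValueError, match="non-empty"):
            train(build_network(cfg.network), [], [s], cfg)


class TestEvaluation:
    @pytest.fixture(scope="class")
    def entries(self):
        out = []
        for seed in (5, 6):
            spec = dataclasses.replace(TINY_SPEC, subject_id=f"e{seed}")
            vol, mask, _ = generate_subject(spec, seed)
            out.append((vol, mask))
        return out

    def test_oracle_predictor_scores_perfectly(self, entries):
        refs = {vol.subject_id: mask for vol, mask in entries}
        report = evaluate_cohort(
            None, entries, predictor=lambda vol: refs[vol.subject_id])
        assert (report.per_subject["dice_sat"] == 1.0).all()
        assert (report.per_subject["dice_vat"] == 1.0).all()
        assert (report.per_subject[["fp_pct", "fn_pct"]] == 0.0).all().all()

    def test_split_leakage_is_a_hard_error(self, entries):
        refs = {vol.subject_id: mask for vol, mask in entries}
        with pytest.raises(RuntimeError, match="leakage"):
            evaluate_cohort(None, entries,
                            train_subject_ids={entries[0][0].subject_id},
                            predictor=lambda v: refs[v.subject_id])

    def test_untrained_model_predicts_valid_labels(self, entries):
        cfg = tiny_config()
        model = build_network(cfg.network)
        pred = predict_mask(model, entries[0][0], cfg)
        assert set(np.unique(pred.labels)) <= {0, 1, 2}
        assert pred.shape == entries[0][1].shape
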