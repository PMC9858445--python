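"""Target-site protocol: balancing, classification rule, metrics, fine-tuning."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score, precision_score

from connsiam._rng import substream
from connsiam.evaluate import (
    EvalProtocol,
    balance_classes,
    classify,
    compute_metrics,
    evaluate_target_sites,
    fine_tune,
    nearest_class_mean,
)
from connsiam.io import ASD, NC
from connsiam.training import SiteDataset, compute_prototypes
from tests.conftest import make_site


class TestBalanceClasses:
    def test_majority_class_downsampled(self, rng):
        feats = rng.normal(size=(20, 4))
        labels = (NC,) * 12 + (ASD,) * 8
        site = SiteDataset("S", feats, labels, tuple(f"s{i}" for i in range(20)))
        balanced = balance_classes(site, substream(0, "bal"))
        assert balanced.class_count(NC) == balanced.class_count(ASD) == 8

    def test_already_balanced_unchanged(self, rng):
        site = make_site("S", 5, 4, rng)
        balanced = balance_classes(site, substream(0, "bal"))
        assert balanced.subject_ids == site.subject_ids

    def test_seed_determinism(self, rng):
        feats = rng.normal(size=(15, 4))
        labels = (NC,) * 10 + (ASD,) * 5
        site = SiteDataset("S", feats, labels, tuple(f"s{i}" for i in range(15)))
        b1 = balance_classes(site, substream(3, "bal"))
        b2 = balance_classes(site, substream(3, "bal"))
        assert b1.subject_ids == b2.subject_ids

    def test_absent_class_errors(self, rng):
        site = SiteDataset("S", rng.normal(size=(3, 4)), (NC, NC, NC), ("a", "b", "c"))
        with pytest.raises(ValueError, match="ASD absent"):
            balance_classes(site, substream(0, "bal"))


class TestClassify:
    def test_query_at_prototype_wins(self, tiny_model, rng):
        baseline = SiteDataset("B", rng.normal(size=(2, 12)), (NC, ASD), ("a", "b"))
        protos = compute_prototypes(tiny_model, baseline)
        label_nc, *_ = classify(tiny_model, baseline.features[0], protos)
        label_asd, *_ = classify(tiny_model, baseline.features[1], protos)
        assert label_nc == NC
        assert label_asd == ASD

    def test_exact_tie_goes_to_asd(self, tiny_model, rng):
        x = rng.normal(size=12)
        baseline = SiteDataset("B", np.vstack([x, x]), (NC, ASD), ("a", "b"))
        protos = compute_prototypes(tiny_model, baseline)
        label, out_nc, out_asd = classify(tiny_model, rng.normal(size=12), protos)
        assert out_nc == out_asd
        assert label == ASD

    def test_stale_prototypes_rejected(self, tiny_model, rng):
        baseline = SiteDataset("B", rng.normal(size=(2, 12)), (NC, ASD), ("a", "b"))
        protos = compute_prototypes(tiny_model, baseline)
        tiny_model.set_params(tiny_model.params)
        with pytest.raises(ValueError, match="stale"):
            classify(tiny_model, rng.normal(size=12), protos)


class TestComputeMetrics:
    def test_all_correct(self):
        preds = [NC, ASD, NC, ASD]
        metrics = compute_metrics(preds, preds)
        assert metrics["accuracy"] == metrics["precision"] == metrics["f1"] == 100.0

    def test_hand_confusion_table(self):
        # tp=3 fp=1 fn=1 tn=5
        truth = [ASD] * 4 + [NC] * 6
        preds = [ASD, ASD, ASD, NC, ASD, NC, NC, NC, NC, NC]
        metrics = compute_metrics(preds, truth)
        assert metrics["accuracy"] == pytest.approx(80.0)
        assert metrics["precision"] == pytest.approx(75.0)
        assert metrics["f1"] == pytest.approx(75.0)
        assert metrics["confusion"] == {"tp": 3, "fp": 1, "fn": 1, "tn": 5}

    def test_no_positive_predictions_convention(self, caplog):
        with caplog.at_level("WARNING"):
            metrics = compute_metrics([NC, NC], [ASD, NC])
        assert metrics["precision"] == 0.0
        assert metrics["f1"] == 0.0

    def test_matches_sklearn_on_random_tables(self, rng):
        """Independent oracle: sklearn with ASD as the positive label."""
        for _ in range(25):
            n = int(rng.integers(4, 30))
            truth = [ASD if rng.random() < 0.5 else NC for _ in range(n)]
            preds = [ASD if rng.random() < 0.5 else NC for _ in range(n)]
            metrics = compute_metrics(preds, truth)
            assert metrics["accuracy"] == pytest.approx(
                100 * accuracy_score(truth, preds)
            )
            assert metrics["precision"] == pytest.approx(
                100 * precision_score(truth, preds, pos_label=ASD, zero_division=0)
            )
            assert metrics["f1"] == pytest.approx(
                100 * f1_score(truth, preds, pos_label=ASD, zero_division=0)
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compute_metrics([NC], [NC, ASD])


class TestFineTune:
    def test_zero_steps_is_identity(self, tiny_model, rng):
        baseline = make_site("B", 3, 12, rng)
        support = make_site("T", 2, 12, rng)
        protocol = EvalProtocol(fine_tune_shots_per_class=2, fine_tune_steps=0)
        tuned = fine_tune(tiny_model, support, baseline, protocol)
        for p1, p2 in zip(tuned.params, tiny_model.params):
            np.testing.assert_array_equal(p1, p2)

    def test_does_not_mutate_input_model(self, tiny_model, rng):
        baseline = make_site("B", 3, 12, rng, offset=1.0)
        support = make_site("T", 3, 12, rng, offset=1.0)
        before = [p.copy() for p in tiny_model.params]
        protocol = EvalProtocol(fine_tune_shots_per_class=3, fine_tune_steps=10)
        tuned = fine_tune(tiny_model, support, baseline, protocol)
        for p1, p2 in zip(before, tiny_model.params):
            np.testing.assert_array_equal(p1, p2)
        assert any(
            not np.array_equal(p1, p2) for p1, p2 in zip(tuned.params, before)
        )

    def test_seed_determinism(self, tiny_model, rng):
        baseline = make_site("B", 3, 12, rng, offset=1.0)
        support = make_site("T", 3, 12, rng, offset=1.0)
        protocol = EvalProtocol(fine_tune_shots_per_class=3, fine_tune_steps=10)
        t1 = fine_tune(tiny_model, support, baseline, protocol)
        t2 = fine_tune(tiny_model, support, baseline, protocol)
        for p1, p2 in zip(t1.params, t2.params):
            np.testing.assert_array_equal(p1, p2)


class TestEvaluateTargetSites:
    def test_support_never_scored_and_report_structure(self, tiny_model, rng):
        tiny_model.fit_scaler(rng.normal(size=(30, 12)))
        baseline = make_site("B", 4, 12, rng, offset=1.0)
        target = make_site("T", 8, 12, rng, offset=1.0)
        protocol = EvalProtocol(fine_tune_shots_per_class=2, fine_tune_steps=5,
                                rng_seed=1)
        report, preds = evaluate_target_sites(
            tiny_model, [target], baseline, protocol
        )
        assert report["T"]["n"] == 12  # 16 balanced minus 4 support
        assert len(preds) == 12
        assert set(preds["site_id"]) == {"T"}
        assert "MACRO" in report

    def test_overlap_with_training_sites_rejected(self, tiny_model, rng):
        baseline = make_site("B", 4, 12, rng)
        target = make_site("S0", 6, 12, rng)
        protocol = EvalProtocol(fine_tune_shots_per_class=0)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_target_sites(
                tiny_model, [target], baseline, protocol, training_site_ids=("S0",)
            )

    def test_too_many_shots_rejected(self, tiny_model, rng):
        baseline = make_site("B", 4, 12, rng)
        target = make_site("T", 3, 12, rng)
        protocol = EvalProtocol(fine_tune_shots_per_class=10, fine_tune_steps=1)
        with pytest.raises(ValueError, match="shots requested"):
            evaluate_target_sites(tiny_model, [target], baseline, protocol)

    def test_end_to_end_determinism(self, tiny_model, rng):
        tiny_model.fit_scaler(rng.normal(size=(30, 12)))
        baseline = make_site("B", 4, 12, rng, offset=1.0)
        target = make_site("T", 8, 12, rng, offset=1.0)
        protocol = EvalProtocol(fine_tune_shots_per_class=2, fine_tune_steps=5,
                                rng_seed=7)
        r1, p1 = evaluate_target_sites(tiny_model, [target], baseline, protocol)
        r2, p2 = evaluate_target_sites(tiny_model, [target], baseline, protocol)
        assert r1 == r2
        assert p1.equals(p2)


def test_siamese_beats_pooled_ncm_under_strong_heterogeneity():
    """When site offsets are large (SD 0.5), the fine-tuned similarity model
    outperforms a pooled nearest-class-mean classifier on mean target-site
    accuracy (10-seed median) -- the multi-site pooling failure mode."""
    from connsiam.benchmark import run_benchmark

    siamese, ncm = [], []
    for seed in range(10):
        result = run_benchmark(
            seed, sim_overrides={"site_effect_sd": 0.5}, with_ncm_baseline=True
        )
        siamese.append(result["mean_target_accuracy"])
        ncm.append(result["ncm_mean_target_accuracy"])
    assert np.median(siamese) > np.median(ncm)


def test_nearest_class_mean_separates_shifted_classes(rng):
    train_x = np.vstack([rng.normal(size=(20, 5)), rng.normal(size=(20, 5)) + 3.0])
    train_y = [NC] * 20 + [ASD] * 20
    query = np.vstack([rng.normal(size=(5, 5)), rng.normal(size=(5, 5)) + 3.0])
    preds = nearest_class_mean(train_x, train_y, query)
    assert preds == [NC] * 5 + [ASD] * 5
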