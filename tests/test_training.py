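"""Meta splits, prototypes, per-site losses, summed objective, training loop."""

import numpy as np
import pytest

from connsiam._rng import substream
from connsiam.io import ASD, NC, RunConfig
from connsiam.model import l1_distance, pair_loss, similarity_output
from connsiam.training import (
    SiteDataset,
    compute_prototypes,
    site_loss,
    split_meta,
    total_loss,
    train,
)
from tests.conftest import make_site


class TestSplitMeta:
    def test_counts_70_30(self, rng):
        site = make_site("S", 10, 4, rng)
        split = split_meta(site, 0.7, substream(0, "split"))
        assert split.meta_train.class_count(NC) == 7
        assert split.meta_train.class_count(ASD) == 7
        assert split.meta_test.class_count(NC) == 3
        assert split.meta_test.class_count(ASD) == 3

    def test_rounding_rule_half_up(self, rng):
        site = make_site("S", 3, 4, rng)
        split = split_meta(site, 0.5, substream(0, "split"))
        # round(0.5 * 3) = 2 per class to meta-train, remainder to meta-test
        assert split.meta_train.class_count(NC) == 2
        assert split.meta_test.class_count(NC) == 1

    def test_disjoint_and_exhaustive(self, rng):
        site = make_site("S", 8, 4, rng)
        split = split_meta(site, 0.7, substream(1, "split"))
        train_ids = set(split.meta_train.subject_ids)
        test_ids = set(split.meta_test.subject_ids)
        assert not train_ids & test_ids
        assert train_ids | test_ids == set(site.subject_ids)

    def test_seed_determinism(self, rng):
        site = make_site("S", 10, 4, rng)
        s1 = split_meta(site, 0.7, substream(5, "split"))
        s2 = split_meta(site, 0.7, substream(5, "split"))
        s3 = split_meta(site, 0.7, substream(6, "split"))
        assert s1.meta_train.subject_ids == s2.meta_train.subject_ids
        assert s1.meta_train.subject_ids != s3.meta_train.subject_ids

    def test_tiny_class_errors_with_site_and_class(self, rng):
        site = SiteDataset("LONELY", rng.normal(size=(3, 4)),
                           (NC, NC, ASD), ("a", "b", "c"))
        with pytest.raises(ValueError, match="LONELY.*ASD"):
            split_meta(site, 0.7, substream(0, "split"))


class TestPrototypes:
    def test_single_sample_prototype_is_its_embedding(self, tiny_model, rng):
        feats = rng.normal(size=(2, 12))
        baseline = SiteDataset("B", feats, (NC, ASD), ("a", "b"))
        protos = compute_prototypes(tiny_model, baseline)
        np.testing.assert_allclose(protos.proto_nc, tiny_model.embed(feats[0]))
        np.testing.assert_allclose(protos.proto_asd, tiny_model.embed(feats[1]))

    def test_duplicated_sample_leaves_prototype_unchanged(self, tiny_model, rng):
        x = rng.normal(size=12)
        other = rng.normal(size=12)
        once = SiteDataset("B", np.vstack([x, other]), (NC, ASD), ("a", "b"))
        twice = SiteDataset("B", np.vstack([x, x, other]), (NC, NC, ASD),
                            ("a", "a2", "b"))
        p1 = compute_prototypes(tiny_model, once)
        p2 = compute_prototypes(tiny_model, twice)
        np.testing.assert_allclose(p1.proto_nc, p2.proto_nc)

    def test_three_sample_mean_by_brute_force(self, tiny_model, rng):
        feats = rng.normal(size=(4, 12))
        baseline = SiteDataset("B", feats, (NC, NC, NC, ASD), tuple("abcd"))
        protos = compute_prototypes(tiny_model, baseline)
        manual = np.mean([tiny_model.embed(feats[i]) for i in range(3)], axis=0)
        np.testing.assert_allclose(protos.proto_nc, manual, atol=1e-12)

    def test_missing_class_errors(self, tiny_model, rng):
        baseline = SiteDataset("B", rng.normal(size=(2, 12)), (NC, NC), ("a", "b"))
        with pytest.raises(ValueError, match="no ASD"):
            compute_prototypes(tiny_model, baseline)


class TestSiteLoss:
    def test_all_outputs_half_gives_eighth(self, tiny_model, rng):
        """If every pair output were 0.5 the mean pair loss is 0.125; realized
        exactly when each sample's embedding coincides with both prototypes."""
        x = rng.normal(size=12)
        baseline = SiteDataset("B", np.vstack([x, x]), (NC, ASD), ("a", "b"))
        meta = SiteDataset("S", np.vstack([x, x]), (NC, ASD), ("c", "d"))
        protos = compute_prototypes(tiny_model, baseline)
        assert site_loss(tiny_model, meta, protos) == pytest.approx(0.125)

    def test_matches_hand_rolled_loop(self, tiny_model, rng):
        baseline = SiteDataset("B", rng.normal(size=(3, 12)), (NC, NC, ASD),
                               ("a", "b", "c"))
        meta = SiteDataset("S", rng.normal(size=(4, 12)), (NC, ASD, ASD, NC),
                           tuple("defg"))
        protos = compute_prototypes(tiny_model, baseline)
        expected = 0.0
        for i, label in enumerate(meta.labels):
            emb = tiny_model.embed(meta.features[i])
            own = protos.proto_nc if label == NC else protos.proto_asd
            other = protos.proto_asd if label == NC else protos.proto_nc
            expected += pair_loss(similarity_output(l1_distance(emb, own)), 0)
            expected += pair_loss(similarity_output(l1_distance(emb, other)), 1)
        expected /= 8
        assert site_loss(tiny_model, meta, protos) == pytest.approx(expected, abs=1e-12)

    def test_stale_prototypes_rejected(self, tiny_model, rng):
        baseline = SiteDataset("B", rng.normal(size=(2, 12)), (NC, ASD), ("a", "b"))
        meta = SiteDataset("S", rng.normal(size=(2, 12)), (NC, ASD), ("c", "d"))
        protos = compute_prototypes(tiny_model, baseline)
        tiny_model.set_params(tiny_model.params)  # any update bumps the version
        with pytest.raises(ValueError, match="stale prototypes"):
            site_loss(tiny_model, meta, protos)


class TestTotalLoss:
    def test_identity_and_sum(self):
        assert total_loss([0.3]) == pytest.approx(0.3)
        assert total_loss([0.1, 0.2, 0.3, 0.4]) == pytest.approx(1.0)

    def test_permutation_invariant(self):
        assert total_loss([0.4, 0.1, 0.3]) == total_loss([0.1, 0.3, 0.4])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            total_loss([])


def _toy_run_config(seed=0, steps=60):
    return RunConfig(
        window_length=10, window_stride=5, n_regions=6,
        encoder_widths=(16, 8), head_widths=(8,), embedding_dim=4,
        n_iterations=steps, rng_seed=seed,
        baseline_site="BASE", training_sites=("S0", "S1"),
    )


class TestTrain:
    def test_loss_decreases_on_learnable_problem(self, toy_sites):
        sites, baseline = toy_sites
        model, history, _ = train(_toy_run_config(steps=120), sites, baseline)
        assert history[-1].total < history[0].total

    def test_total_equals_sum_of_parts_every_step(self, toy_sites):
        sites, baseline = toy_sites
        _, history, _ = train(_toy_run_config(steps=30), sites, baseline)
        for report in history:
            assert report.total == pytest.approx(sum(report.per_site.values()),
                                                 abs=1e-9)

    def test_same_seed_identical_history(self, toy_sites):
        sites, baseline = toy_sites
        _, h1, _ = train(_toy_run_config(seed=3, steps=40), sites, baseline)
        _, h2, _ = train(_toy_run_config(seed=3, steps=40), sites, baseline)
        assert [r.total for r in h1] == [r.total for r in h2]

    def test_baseline_among_training_sites_rejected(self, toy_sites):
        sites, baseline = toy_sites
        with pytest.raises(ValueError, match="must not be among"):
            train(_toy_run_config(), sites + [baseline], baseline)

    def test_meta_test_never_updates_parameters(self, toy_sites):
        """Scoring the meta-test sets must not touch the parameters: a run
        with per-step evaluation matches one that never evaluates."""
        sites, baseline = toy_sites
        m1, _, _ = train(_toy_run_config(seed=2, steps=30), sites, baseline,
                         eval_interval=1)
        m2, _, _ = train(_toy_run_config(seed=2, steps=30), sites, baseline,
                         eval_interval=0)
        for p1, p2 in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p1, p2)
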