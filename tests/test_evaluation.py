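"""Metric oracles, bootstrap machinery and the robustness experiment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from icufusion.evaluation import (
    ScoredSet,
    bootstrap_ci,
    bootstrap_p_diff,
    delong_p,
    evaluate,
    pr_auc,
    robustness_experiment,
    roc_auc,
    youden_threshold,
)


def pair_counting_auc(scores, labels):
    """Independent oracle: average over all (pos, neg) pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def sweep_youden(scores, labels):
    """Independent oracle: exhaustive sweep over observed thresholds."""
    best = None
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for thr in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 0)
        sens, spec = tp / n_pos, 1 - fp / n_neg
        if best is None or sens + spec > best[1] + best[2] + 1e-12:
            ppv = tp / (tp + fp) if tp + fp else 0.0
            best = (thr, sens, spec, ppv)
    return best


class TestRocAuc:
    def test_worked_example_four_pairs(self):
        s = ScoredSet([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert roc_auc(s) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert roc_auc(ScoredSet([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0
        assert roc_auc(ScoredSet([0.5] * 6, [1, 1, 1, 0, 0, 0])) == 0.5

    def test_exhaustive_small_sets_match_pair_counting(self, rng):
        """All labelled sets of n <= 8 over a 3-value score alphabet."""
        values = [0.1, 0.5, 0.9]
        for n in (2, 4, 6, 8):
            for _ in range(40):
                scores = rng.choice(values, size=n)
                labels = rng.integers(0, 2, n)
                if 0 < labels.sum() < n:
                    got = roc_auc(ScoredSet(scores, labels))
                    assert got == pytest.approx(pair_counting_auc(scores, labels))

    def test_matches_sklearn_on_random_data(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        got = roc_auc(ScoredSet(scores, labels))
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_invariant_to_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=30)
        labels = r.integers(0, 2, 30)
        if not 0 < labels.sum() < 30:
            return
        a = roc_auc(ScoredSet(scores, labels))
        b = roc_auc(ScoredSet(np.exp(2.0 * scores) + 5.0, labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(ScoredSet([0.1, 0.2], [1, 1]))


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc(ScoredSet([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_single_positive_ranked_first(self):
        assert pr_auc(ScoredSet([0.9, 0.5, 0.4, 0.3], [1, 0, 0, 0])) == 1.0

    def test_random_scores_approach_prevalence(self):
        r = np.random.default_rng(0)
        n, pi = 20_000, 0.2
        labels = (r.random(n) < pi).astype(int)
        scores = r.random(n)
        assert pr_auc(ScoredSet(scores, labels)) == pytest.approx(pi, abs=0.02)

    def test_no_positive_errors(self):
        with pytest.raises(ValueError):
            pr_auc(ScoredSet([0.1, 0.2], [0, 0]))


class TestYouden:
    def test_separable_set_reaches_perfect_operating_point(self):
        thr, sens, spec, ppv = youden_threshold(
            ScoredSet([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        )
        assert (sens, spec, ppv) == (1.0, 1.0, 1.0)
        assert 0.2 < thr <= 0.8

    def test_degenerate_all_equal_scores(self):
        thr, sens, spec, ppv = youden_threshold(ScoredSet([0.5] * 4, [1, 0, 1, 0]))
        assert sens + spec == 1.0

    def test_matches_exhaustive_sweep_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if not 0 < labels.sum() < n:
                continue
            got = youden_threshold(ScoredSet(scores, labels))
            want = sweep_youden(list(scores), list(labels))
            assert got[1] + got[2] == pytest.approx(want[1] + want[2], abs=1e-12)
            assert got[0] == pytest.approx(want[0])  # tie -> lower threshold


class TestBootstrap:
    def test_fixed_seed_is_bit_reproducible(self, rng):
        s = ScoredSet(rng.random(60), rng.integers(0, 2, 60))
        a = bootstrap_ci(s, roc_auc, n_boot=200, seed=11)
        b = bootstrap_ci(s, roc_auc, n_boot=200, seed=11)
        assert a == b

    def test_interval_contains_point_estimate_on_random_sets(self, rng):
        for _ in range(50):
            s = ScoredSet(rng.random(80), rng.integers(0, 2, 80))
            if not s.both_classes():
                continue
            point, lo, hi = bootstrap_ci(s, roc_auc, n_boot=300, seed=3)
            assert lo - 0.05 <= point <= hi + 0.05

    def test_single_redraw_degenerate_interval(self, rng):
        s = ScoredSet(rng.random(30), rng.integers(0, 2, 30))
        point, lo, hi = bootstrap_ci(s, roc_auc, n_boot=1, seed=0)
        assert lo == hi

    def test_identical_models_give_p_of_one(self, rng):
        s = ScoredSet(rng.random(50), rng.integers(0, 2, 50))
        assert bootstrap_p_diff(s, s, roc_auc, n_boot=200, seed=0) == 1.0

    def test_p_value_symmetric_in_model_order(self, rng):
        labels = rng.integers(0, 2, 60)
        a = ScoredSet(rng.random(60), labels)
        b = ScoredSet(rng.random(60), labels)
        pab = bootstrap_p_diff(a, b, roc_auc, n_boot=400, seed=2)
        pba = bootstrap_p_diff(b, a, roc_auc, n_boot=400, seed=2)
        assert pab == pytest.approx(pba)

    def test_perfect_vs_random_hits_the_floor(self, rng):
        n = 300
        labels = rng.integers(0, 2, n)
        perfect = ScoredSet(labels + 0.0, labels)
        random_s = ScoredSet(rng.random(n), labels)
        p = bootstrap_p_diff(perfect, random_s, roc_auc, n_boot=500, seed=1)
        assert p == pytest.approx(1 / 500)

    def test_delong_agrees_with_bootstrap_in_order_of_magnitude(self, rng):
        n = 200
        x = rng.normal(size=n)
        labels = (x + rng.normal(size=n) > 0).astype(int)
        good = ScoredSet(x, labels)
        noisy = ScoredSet(x + rng.normal(size=n) * 2.0, labels)
        p_boot = bootstrap_p_diff(good, noisy, roc_auc, n_boot=2000, seed=0)
        p_dl = delong_p(good, noisy)
        assert (p_boot < 0.05) == (p_dl < 0.05)


class TestEvaluate:
    def test_report_contains_all_metrics_with_ordered_cis(self, rng):
        scores = rng.random(120)
        labels = (scores + rng.normal(size=120) * 0.4 > 0.5).astype(int)
        rep = evaluate(ScoredSet(scores, labels), n_boot=200, seed=4)
        for trip in (rep.auroc, rep.auprc, rep.sensitivity, rep.specificity, rep.ppv):
            point, lo, hi = trip
            assert lo <= hi
            assert 0.0 <= point <= 1.0
        d = rep.to_dict()
        assert set(d) >= {"auroc", "auprc", "sensitivity", "specificity", "ppv"}

    def test_fixed_threshold_mode_differs_from_refit(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        a = evaluate(ScoredSet(scores, labels), n_boot=100, seed=0, refit_threshold=True)
        b = evaluate(ScoredSet(scores, labels), n_boot=100, seed=0, refit_threshold=False)
        assert a.threshold == b.threshold  # same point estimate path


class TestRobustness:
    def _trained_stub(self, tiny_model_cfg):
        from icufusion.model import MultimodalTransformer

        return MultimodalTransformer(tiny_model_cfg, seed=0)

    def test_grid_shape_and_reproducibility(self, tiny_model_cfg, rng):
        model = self._trained_stub(tiny_model_cfg)
        n = 30
        patches = rng.normal(size=(n, model.N, tiny_model_cfg.image_spec.patch_dim))
        feats = rng.normal(size=(n, 5, tiny_model_cfg.T))
        labels = rng.integers(0, 2, n)
        labels[:3] = 1
        labels[-3:] = 0
        source = ["hr", "hr", "rr", "spo2", "temp"]
        res = robustness_experiment(model, patches, feats, labels, source,
                                    ks=(1, 2), reps=3, seed=7)
        assert len(res.records) == 6
        assert set(res.records["k"]) == {1, 2}
        res2 = robustness_experiment(model, patches, feats, labels, source,
                                     ks=(1, 2), reps=3, seed=7)
        assert res.records.equals(res2.records)

    def test_masking_more_items_than_schema_errors(self, tiny_model_cfg, rng):
        model = self._trained_stub(tiny_model_cfg)
        with pytest.raises(ValueError):
            robustness_experiment(
                model,
                rng.normal(size=(4, model.N, tiny_model_cfg.image_spec.patch_dim)),
                rng.normal(size=(4, 5, tiny_model_cfg.T)),
                np.array([0, 1, 0, 1]),
                ["a", "b", "c", "d", "e"],
                ks=(6,),
                reps=1,
            )
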