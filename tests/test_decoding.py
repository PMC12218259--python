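"""Surrogate rasters, balanced linear decoding and classification metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import popcode
from popcode.core import EventRaster
from popcode.decoding import (
    DecodeTask,
    metrics,
    surrogate_shuffle,
    train_eval,
    transfer_eval,
    weight_modulation_correlation,
)
from popcode.modulation import ModulationVector, behavior_modulation

from conftest import small_social_session


class TestSurrogate:
    @given(st.integers(0, 10_000))
    def test_margins_preserved_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((rng.integers(2, 12), rng.integers(2, 40))) < 0.2).astype(int)
        r = EventRaster(m, 20.0)
        s = surrogate_shuffle(r, seed=seed)
        assert np.array_equal(s.values.sum(0), m.sum(0))
        assert np.array_equal(s.values.sum(1), m.sum(1))

    def test_all_ones_unchanged(self):
        r = EventRaster(np.ones((3, 4), int), 20.0)
        s = surrogate_shuffle(r, seed=0)
        assert np.array_equal(s.values, r.values)

    def test_identity_pattern_visits_both_configurations(self):
        m = np.eye(2, dtype=int)
        seen = set()
        for seed in range(40):
            s = surrogate_shuffle(EventRaster(m, 20.0), seed=seed)
            seen.add(tuple(s.values.ravel()))
        # the margin-preserving state space is exactly {identity, anti-identity}
        assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}


class TestMetrics:
    def test_direct_evaluation(self):
        m = metrics(tp=1, fp=1, fn=3)
        assert m["precision"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(0.25)
        assert m["f1"] == pytest.approx(1 / 3)

    def test_perfect_scores(self):
        m = metrics(tp=10, fp=0, fn=0)
        assert m["f1"] == 1.0

    def test_undefined_precision_flagged_not_zeroed(self):
        m = metrics(tp=0, fp=0, fn=5)
        assert not m["precision_defined"]
        assert np.isnan(m["precision"])
        assert m["recall"] == 0.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        m = metrics(tp, fp, fn)
        if m["f1_defined"]:
            assert min(m["precision"], m["recall"]) - 1e-12 <= m["f1"]
            assert m["f1"] <= max(m["precision"], m["recall"]) + 1e-12


class TestTrainEval:
    def test_perfectly_separable_neuron(self):
        T = 400
        soc = np.zeros(T, bool); soc[:200] = True
        r = np.zeros((5, T), int)
        r[0, soc] = 1  # active iff social
        res = train_eval(
            EventRaster(r, 20.0), DecodeTask(soc, ~soc, n_iterations=10, seed=0)
        )
        assert res.accuracy_mean > 0.95

    def test_surrogate_input_chance_accuracy(self, social_session):
        ann = social_session.annotation
        surr = surrogate_shuffle(social_session.raster, seed=1)
        task = DecodeTask(ann.social_mask(), ann.nonsocial_mask(),
                          n_iterations=30, seed=2)
        res = train_eval(surr, task)
        assert abs(res.accuracy_mean - 0.5) < 0.03

    def test_accuracy_matches_bayes_oracle_on_known_rates(self):
        rng = np.random.default_rng(5)
        n, T = 30, 6000
        r_pos = rng.uniform(0.01, 0.08, n)
        r_neg = r_pos * rng.choice([0.4, 1.0, 2.5], n)
        y = np.arange(T) % 2 == 0
        X = np.empty((n, T), dtype=int)
        X[:, y] = rng.random((n, y.sum())) < r_pos[:, None]
        X[:, ~y] = rng.random((n, (~y).sum())) < r_neg[:, None]
        # closed-form Bayes classifier on the true generative rates,
        # evaluated by Monte Carlo on fresh draws
        w = np.log(r_pos / r_neg) - np.log((1 - r_pos) / (1 - r_neg))
        b = np.log((1 - r_pos) / (1 - r_neg)).sum()
        M = 200_000
        xs_pos = rng.random((M, n)) < r_pos
        xs_neg = rng.random((M, n)) < r_neg
        bayes = 0.5 * ((xs_pos @ w + b > 0).mean() + (xs_neg @ w + b <= 0).mean())
        res = train_eval(EventRaster(X, 20.0), DecodeTask(y, ~y, n_iterations=20, seed=6))
        assert abs(res.accuracy_mean - bayes) < 0.03

    def test_empty_class_raises(self):
        r = EventRaster(np.zeros((2, 10), int), 20.0)
        with pytest.raises(ValueError, match="zero frames"):
            train_eval(r, DecodeTask(np.zeros(10, bool), np.ones(10, bool), n_iterations=1))


class TestTransfer:
    @staticmethod
    def _cross_context_acc(session, n_iter=25):
        ann = session.annotation
        task = DecodeTask(ann.social_mask(["A"]), ann.nonsocial_mask(["A"]),
                          n_iterations=n_iter, seed=3)
        tests = [
            ("B", ann.social_mask(["B"]), ann.nonsocial_mask(["B"])),
            ("C", ann.social_mask(["C"]), ann.nonsocial_mask(["C"])),
        ]
        res = transfer_eval(session.raster, task, tests, "A")
        return {r.test_scope: r for r in res}

    def test_remap_off_transfers_above_chance(self, social_session):
        res = self._cross_context_acc(social_session)
        # binomial 99% bound on the mean accuracy over all tested frames
        r = res["C"]
        n_tested = r.n_iterations * 200  # conservative lower bound on frames
        assert r.accuracy_mean > 0.5 + 2.58 * np.sqrt(0.25 / n_tested)

    def test_remap_on_cross_context_at_chance_within_above(self, remap_session):
        res = self._cross_context_acc(remap_session)
        assert abs(res["C"].accuracy_mean - 0.5) < 0.03  # other context: chance
        assert res["B"].accuracy_mean > res["C"].accuracy_mean  # same context better

    def test_overlapping_scopes_rejected(self, social_session):
        ann = social_session.annotation
        task = DecodeTask(ann.social_mask(["A"]), ann.nonsocial_mask(["A"]),
                          n_iterations=2, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            transfer_eval(
                social_session.raster, task,
                [("A", ann.social_mask(["A"]), ann.nonsocial_mask(["A"]))],
            )


class TestWeightModulationCorrelation:
    def test_planted_gains_give_positive_correlation(self, social_session):
        ann = social_session.annotation
        task = DecodeTask(ann.social_mask(), ann.nonsocial_mask(),
                          n_iterations=20, seed=4)
        res = train_eval(social_session.raster, task)
        mv = behavior_modulation(
            social_session.raster, ann, ("A", "B", "C", "D"), "social",
            "mean-difference", n_shuffles=500, seed=5,
        )
        r, p = weight_modulation_correlation(res, mv)
        assert r > 0.3
        assert p < 0.01

    def test_shuffled_pairing_destroys_correlation(self, social_session):
        ann = social_session.annotation
        task = DecodeTask(ann.social_mask(), ann.nonsocial_mask(),
                          n_iterations=20, seed=4)
        res = train_eval(social_session.raster, task)
        mv = behavior_modulation(
            social_session.raster, ann, ("A", "B", "C", "D"), "social",
            "mean-difference", n_shuffles=500, seed=5,
        )
        rng = np.random.default_rng(0)
        shuffled = ModulationVector(
            rng.permutation(mv.index), mv.excluded, mv.scope, mv.contrast
        )
        r, _ = weight_modulation_correlation(res, shuffled)
        assert abs(r) < 0.25

    def test_identical_vectors_give_unity(self):
        from popcode.decoding import DecodingResult
        idx = np.linspace(5, 95, 20)
        res = DecodingResult("a", "a", 0.6, 0.01, 0.6, 0.6, 0.6, 1, beta_mean=idx.copy())
        mv = ModulationVector(idx, np.zeros(20, bool), ("A",), "social")
        r, _ = weight_modulation_correlation(res, mv)
        assert r == pytest.approx(1.0)
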