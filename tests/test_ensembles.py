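"""Population vectors, activity summaries and similarity matrices."""

import numpy as np
import pytest

import popcode
from popcode.core import EventRaster, CalciumTraces
from popcode.ensembles import (
    HIGHLY_ACTIVE_THRESHOLD,
    PopulationVector,
    activity_summary,
    filter_active_both,
    population_vector,
    similarity_matrix,
    within_between_summary,
)
from popcode.events import zscore_traces

from conftest import small_social_session


def raster(arr):
    return EventRaster(np.asarray(arr), 20.0)


class TestPopulationVector:
    def test_hand_counted_fractions(self):
        r = raster([[1, 1, 0, 1, 0, 0, 0, 0, 0, 0],
                    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0]])
        mask = np.zeros(10, bool)
        mask[:5] = True
        v = population_vector(r, mask, "cond")
        assert v.values[0] == pytest.approx(0.6)
        assert v.values[1] == 0.0
        assert v.n_frames == 5

    def test_all_ones_raster_gives_unit_vector(self):
        r = raster(np.ones((3, 8)))
        v = population_vector(r, np.arange(8) % 2 == 0)
        assert (v.values == 1.0).all()

    def test_empty_mask_raises_with_condition_name(self):
        r = raster(np.ones((2, 4)))
        with pytest.raises(ValueError, match="social"):
            population_vector(r, np.zeros(4, bool), "social")

    def test_linearity_averaging_equal_masks(self):
        rng = np.random.default_rng(0)
        r = raster(rng.integers(0, 2, (5, 100)))
        m1 = np.zeros(100, bool); m1[:40] = True
        m2 = np.zeros(100, bool); m2[40:80] = True
        v1 = population_vector(r, m1).values
        v2 = population_vector(r, m2).values
        v12 = population_vector(r, m1 | m2).values
        assert np.allclose(v12, (v1 + v2) / 2)


class TestActivitySummary:
    def test_identical_masks_give_zero_ks(self):
        rng = np.random.default_rng(1)
        r = raster(rng.integers(0, 2, (10, 50)))
        m = np.ones(50, bool)
        out = activity_summary(r, {"a": m, "b": m.copy()})
        assert out.loc[1, "ks_vs_first"] == 0.0

    def test_threshold_is_strict(self):
        # neuron active exactly 7.5% of frames is NOT highly active
        r = raster(np.r_[np.ones((1, 3)), np.zeros((1, 3))].T.reshape(1, 6) * 0)
        v = np.zeros((2, 40), dtype=int)
        v[0, :3] = 1   # 3/40 = 7.5% exactly
        v[1, :4] = 1   # 10% => highly active
        out = activity_summary(raster(v), {"all": np.ones(40, bool)})
        assert out.loc[0, "n_highly_active"] == 1

    def test_planted_gains_shift_both_tails(self):
        truth = popcode.TruthConfig(social_frac_pos=0.25, social_frac_neg=0.25,
                                    social_gain_pos=3.0, social_gain_neg=1 / 3)
        s = small_social_session(seed=13, truth=truth, n_neurons=100)
        ann = s.annotation
        out = activity_summary(
            s.raster,
            {"nonsocial": ann.nonsocial_mask(), "social": ann.social_mask()},
        )
        assert out.loc[1, "ks_vs_first"] > 0
        assert out.loc[1, "ks_pvalue_vs_first"] < 0.05


class TestSimilarityMatrix:
    def test_self_similarity_and_antilinearity(self):
        a = PopulationVector("a", np.array([0.1, 0.2, 0.3]), 10)
        b = PopulationVector("b", np.array([0.3, 0.2, 0.1]), 10)
        sim = similarity_matrix([a, b])
        assert sim.pair("a", "a") == pytest.approx(1.0)
        assert sim.pair("a", "b") == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_on_fixture(self, social_session):
        ann = social_session.annotation
        vecs = [
            population_vector(social_session.raster, ann.social_mask([e]), f"{e}:social")
            for e in "ABCD"
        ]
        sim = similarity_matrix(vecs)
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)
        assert (np.abs(sim.values) <= 1 + 1e-12).all()

    def test_too_few_vectors_raises(self):
        v = PopulationVector("a", np.array([0.1, 0.2]), 5)
        with pytest.raises(ValueError):
            similarity_matrix([v])

    def test_raster_and_trace_modes_agree_in_structure(self):
        truth = popcode.TruthConfig(social_frac_pos=0.25, social_frac_neg=0.25,
                                    social_gain_pos=4.0, social_gain_neg=0.25)
        s = small_social_session(seed=17, truth=truth, n_neurons=80)
        ann = s.annotation
        z, _ = zscore_traces(s.traces)
        conds = [(e, b) for e in "ABCD" for b in ("social", "nonsocial")]
        masks = {
            f"{e}:{b}": (ann.social_mask([e]) if b == "social" else ann.nonsocial_mask([e]))
            for e, b in conds
        }
        sim_r = similarity_matrix(
            [population_vector(s.raster, m, k) for k, m in masks.items()]
        ).values
        sim_t = similarity_matrix(
            [population_vector(z, m, k) for k, m in masks.items()]
        ).values
        iu = np.triu_indices_from(sim_r, k=1)
        r = np.corrcoef(sim_r[iu], sim_t[iu])[0, 1]
        assert r > 0.5  # same similarity structure from rasters and z-scored traces


class TestWithinBetween:
    @staticmethod
    def _summary(session):
        ann = session.annotation
        vecs = []
        for e in "ABCD":
            vecs.append(population_vector(session.raster, ann.social_mask([e]), f"{e}:social"))
            vecs.append(
                population_vector(session.raster, ann.nonsocial_mask([e]), f"{e}:nonsocial")
            )
        sim = similarity_matrix(vecs)
        ctx = {e: ann.context_of(e) for e in "ABCD"}
        return within_between_summary(sim, ctx)

    def test_identical_vectors_within_equals_between(self):
        vecs = [
            PopulationVector(f"{e}:social", np.array([0.1, 0.5, 0.9]), 5) for e in "ABCD"
        ]
        sim = similarity_matrix(vecs)
        wb = within_between_summary(sim, {"A": "c1", "B": "c1", "C": "c2", "D": "c2"})
        row = wb.iloc[0]
        assert row["within_context"] == pytest.approx(1.0)
        assert row["between_context"] == pytest.approx(1.0)

    def test_no_context_effect_between_matches_within(self):
        truth = popcode.TruthConfig(context_frac_pos=0, context_frac_neg=0)
        s = small_social_session(seed=19, truth=truth, n_neurons=100)
        wb = self._summary(s)
        soc = wb[(wb.type_a == "social") & (wb.type_b == "social")].iloc[0]
        assert abs(soc["within_context"] - soc["between_context"]) < 0.15

    def test_context_gain_reduces_between_similarity(self):
        truth = popcode.TruthConfig(context_frac_pos=0.25, context_frac_neg=0.25,
                                    context_gain_pos=3.0, context_gain_neg=1 / 3)
        s = small_social_session(seed=19, truth=truth, n_neurons=100)
        wb = self._summary(s)
        soc = wb[(wb.type_a == "social") & (wb.type_b == "social")].iloc[0]
        assert soc["between_context"] < soc["within_context"] - 0.1


class TestFilterActiveBoth:
    def test_context_silent_neurons_excluded(self, social_session):
        r = social_session.raster.values.copy()
        ann = social_session.annotation
        silent = np.arange(10)
        r[np.ix_(silent, ann.context_mask("ctx2"))] = 0
        # ensure they are active somewhere in ctx1
        r[silent, 0] = 1
        keep = filter_active_both(EventRaster(r, 20.0), ann)
        assert set(silent).isdisjoint(keep)

    def test_all_active_gives_identity(self):
        ann = small_social_session(seed=2, n_neurons=4, pre_frames=100, n_bouts=1,
                                   bout_frames=100, gap_frames=50,
                                   baseline_frames=0).annotation
        r = EventRaster(np.ones((4, ann.n_frames), dtype=int), 20.0)
        assert np.array_equal(filter_active_both(r, ann), np.arange(4))
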