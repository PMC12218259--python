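"""Circular-shift nulls and percentile modulation indices."""

import numpy as np
import pytest
from scipy import stats

import popcode
from popcode.core import EventRaster
from popcode.modulation import (
    behavior_modulation,
    circular_null,
    circular_shift_stats,
    context_modulation,
    modulation_index,
)

from conftest import small_social_session


def enumerate_null(row, mask):
    """Brute-force mean-in-mask statistic for every circular shift."""
    T = len(row)
    out = []
    for s in range(T):
        shifted = np.roll(row, s)
        out.append(shifted[mask].mean())
    return np.array(out)


class TestCircularNull:
    def test_exhaustive_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            T = rng.integers(4, 24)
            row = rng.integers(0, 2, T)
            mask = np.zeros(T, bool)
            mask[rng.choice(T, rng.integers(1, T), replace=False)] = True
            null = circular_null(row, mask, exhaustive=True)
            expect = enumerate_null(row, mask)
            assert np.array_equal(np.sort(null.values[0]), np.sort(expect))

    def test_twelve_frame_example_multiset(self):
        row = np.zeros(12, int)
        row[:2] = 1
        mask = np.zeros(12, bool)
        mask[:4] = True
        null = circular_null(row, mask, exhaustive=True)
        vals = np.sort(null.values[0])
        assert np.array_equal(vals, np.sort([0.5] * 3 + [0.25] * 2 + [0.0] * 7))

    def test_twelve_frame_index_is_87_5(self):
        row = np.zeros(12, int)
        row[:2] = 1
        mask = np.zeros(12, bool)
        mask[:4] = True
        null = circular_null(row, mask, exhaustive=True)
        assert modulation_index(0.5, null)[0] == pytest.approx(87.5)

    def test_always_active_neuron_degenerate_null_gives_50(self):
        row = np.ones(30, int)
        mask = np.zeros(30, bool)
        mask[:10] = True
        null = circular_null(row, mask, n_shuffles=100, seed=0)
        assert (null.values == 1.0).all()
        assert modulation_index(1.0, null)[0] == pytest.approx(50.0)

    def test_event_count_preserved_under_every_shift(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 2, 50)
        stats_all = circular_shift_stats(row[None, :], np.ones(50, bool))
        assert np.allclose(stats_all, row.mean())

    def test_sampled_null_converges_to_enumeration(self):
        rng = np.random.default_rng(2)
        row = rng.integers(0, 2, 20)
        mask = np.zeros(20, bool)
        mask[:7] = True
        exact = enumerate_null(row, mask)
        null = circular_null(row, mask, n_shuffles=20000, seed=3)
        # total-variation distance between sampled and exact distributions
        support = np.unique(exact)
        p = np.array([(exact == v).mean() for v in support])
        q = np.array([(null.values[0] == v).mean() for v in support])
        assert null.values[0].size == 20000
        assert 0.5 * np.abs(p - q).sum() < 0.03

    def test_scope_too_short_raises(self):
        with pytest.raises(ValueError):
            circular_null(np.array([1]), np.array([True]))

    def test_observed_above_all_nulls_maps_to_extremum(self):
        null = circular_null(
            np.r_[np.ones(5, int), np.zeros(15, int)],
            np.r_[np.ones(5, bool), np.zeros(15, bool)],
            n_shuffles=200, seed=4,
        )
        idx = modulation_index(np.array([2.0]), null)  # above every null value
        assert idx[0] == pytest.approx(100.0)
        # strictly largest finite statistic: 100 * (1 - 0.5/n)
        top = null.values[0].max()
        below = (null.values[0] < top).sum()
        ties = (null.values[0] == top).sum()
        assert modulation_index(np.array([top]), null)[0] == pytest.approx(
            100 * (below + 0.5 * ties) / 200
        )


class TestBehaviorModulation:
    def test_planted_gains_recovered_in_tails(self, social_session):
        mv = behavior_modulation(
            social_session.raster, social_session.annotation, ("A", "B"),
            "social", "mean-difference", n_shuffles=1000, seed=0,
        )
        lab = social_session.truth.social_labels("ctx1")
        ok = mv.valid()
        assert np.nanmedian(mv.index[(lab > 0) & ok]) > 90
        assert np.nanmedian(mv.index[(lab < 0) & ok]) < 10

    def test_null_population_uniform_indices(self, null_session):
        mv = behavior_modulation(
            null_session.raster, null_session.annotation, ("A", "B"),
            "social", "mean-in-mask", n_shuffles=1000, seed=1,
        )
        idx = mv.index[mv.valid()]
        frac_hi = (idx > 90).mean()
        assert abs(frac_hi - 0.10) < 0.10
        ks = stats.kstest(idx / 100, "uniform")
        assert ks.statistic < 1.63 / np.sqrt(len(idx))  # alpha=0.01 critical value

    def test_inactive_neurons_removed(self):
        s = small_social_session(seed=33, n_neurons=10)
        r = s.raster.values.copy()
        r[3] = 0
        mv = behavior_modulation(
            EventRaster(r, 20.0), s.annotation, ("A", "B"), "social",
            "mean-difference", n_shuffles=200, seed=0,
        )
        assert mv.excluded[3]
        assert np.isnan(mv.index[3])

    def test_absent_behavior_raises(self, social_session):
        with pytest.raises(ValueError, match="absent|unknown"):
            behavior_modulation(
                social_session.raster, social_session.annotation, ("A",),
                "grooming", n_shuffles=10, seed=0,
            )


class TestContextModulation:
    def test_planted_context_gain_shifts_index_down(self):
        truth = popcode.TruthConfig(
            social_frac_pos=0, social_frac_neg=0,
            context_frac_pos=0.3, context_frac_neg=0, context_gain_pos=2.0,
        )
        s = small_social_session(seed=29, truth=truth, n_neurons=60)
        mv = context_modulation(
            s.raster, s.annotation, (("A", "B"), ("C", "D")), n_shuffles=1000, seed=0
        )
        lab = s.truth.context_labels("ctx2")
        # gain 2 in context CD => AB-minus-CD difference strongly negative
        assert np.nanmedian(mv.index[lab > 0]) < 10
        assert 30 < np.nanmedian(mv.index[lab == 0]) < 70

    def test_no_context_effect_uniform(self, null_session):
        mv = context_modulation(
            null_session.raster, null_session.annotation, (("A", "B"), ("C", "D")),
            n_shuffles=1000, seed=2,
        )
        idx = mv.index[mv.valid()]
        assert abs((idx > 90).mean() - 0.10) < 0.10

    def test_swapped_split_antisymmetric_under_exhaustive_shifts(self):
        s = small_social_session(seed=31, n_neurons=12, pre_frames=150, n_bouts=2,
                                 bout_frames=150, gap_frames=50, baseline_frames=0)
        fwd = context_modulation(
            s.raster, s.annotation, (("A", "B"), ("C", "D")), exhaustive=True
        )
        rev = context_modulation(
            s.raster, s.annotation, (("C", "D"), ("A", "B")), exhaustive=True
        )
        ok = fwd.valid() & rev.valid()
        assert np.allclose(fwd.index[ok] + rev.index[ok], 100.0)

    def test_remap_invariance_readout(self, social_session, remap_session):
        def ab_cd_r(session):
            ab = behavior_modulation(
                session.raster, session.annotation, ("A", "B"), "social",
                "mean-difference", n_shuffles=500, seed=5,
            )
            cd = behavior_modulation(
                session.raster, session.annotation, ("C", "D"), "social",
                "mean-difference", n_shuffles=500, seed=6,
            )
            ok = ab.valid() & cd.valid()
            return np.corrcoef(ab.index[ok], cd.index[ok])[0, 1]

        assert ab_cd_r(social_session) > 0.2  # shared ensemble across contexts
        assert abs(ab_cd_r(remap_session)) < 0.2  # redrawn ensemble decorrelates
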