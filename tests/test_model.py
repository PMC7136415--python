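"""Transition counting, ML estimation, and the geometric bout law."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boutmarkov as bm
from boutmarkov.records import ACTIVE, DAY, NIGHT, REST

from conftest import make_seq


def brute_force_counts(states, phases, gap_after=None):
    """Oracle: enumerate every adjacent pair literally."""
    table = np.zeros((2, 2, 2), dtype=int)
    for i in range(len(states) - 1):
        if gap_after is not None and gap_after[i]:
            continue
        table[phases[i], states[i], states[i + 1]] += 1
    return table


class TestCountTransitions:
    def test_hand_enumeration(self):
        counts = bm.count_transitions(make_seq("RRAARA"))
        assert counts.n_rr(DAY) == 1
        assert counts.n_ra(DAY) == 2
        assert counts.n_aa(DAY) == 1
        assert counts.n_ar(DAY) == 1
        assert counts.total_pairs == 5

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_all_rest(self, k):
        counts = bm.count_transitions(make_seq("R" * k))
        assert counts.n_rr(DAY) == k - 1
        assert counts.total_pairs == k - 1

    def test_phase_boundary_uses_origin_bin(self):
        # the single R->A transition happens out of a DAY bin
        counts = bm.count_transitions(make_seq("RA", "DN"))
        assert counts.n_ra(DAY) == 1
        assert counts.table[NIGHT].sum() == 0

    def test_too_short(self):
        with pytest.raises(bm.ValidationError):
            bm.count_transitions(make_seq("R"))

    def test_gap_pairs_excluded(self):
        gap = np.zeros(6, bool)
        gap[2] = True
        counts = bm.count_transitions(make_seq("RRARRA", gap_after=gap))
        no_gap = bm.count_transitions(make_seq("RRARRA"))
        assert counts.total_pairs == 4
        assert no_gap.total_pairs == 5

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(2, 20))
        states = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        phases = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        gaps = data.draw(st.lists(st.booleans(), min_size=n - 1, max_size=n - 1))
        gap_after = np.array(gaps + [False])
        seq = bm.EncodedSequence("h", 10, states=states, phase=phases, gap_after=gap_after)
        assert np.array_equal(
            bm.count_transitions(seq).table,
            brute_force_counts(states, phases, gap_after),
        )


class TestFitMarkov:
    def test_hand_example(self):
        res = bm.TwoStateMarkov(make_seq("RRAARA")).fit()
        assert res.alpha[DAY] == pytest.approx(2 / 3)
        assert res.beta[DAY] == pytest.approx(1 / 2)

    def test_mean_rest_bout_unit_conversion(self):
        # alpha = 1/6 per 10-s bin -> mean rest bout exactly one minute
        table = np.zeros((2, 2, 2), int)
        table[DAY, REST, ACTIVE] = 1
        table[DAY, REST, REST] = 5
        table[DAY, ACTIVE, REST] = 1
        res = bm.fit_markov(bm.TransitionCounts(table), bin_seconds=10)
        assert res.mean_rest_bout_min[DAY] == pytest.approx(1.0)

    def test_bin_seconds_generalization(self):
        table = np.zeros((2, 2, 2), int)
        table[DAY, REST, ACTIVE] = 1
        table[DAY, REST, REST] = 5
        res = bm.fit_markov(bm.TransitionCounts(table), bin_seconds=30)
        assert res.mean_rest_bout_min[DAY] == pytest.approx(3.0)

    def test_reference_ld_night_activity(self):
        # transition probabilities implied by the LD-night cohort bout means
        # put the animal in the active state 30% of the night
        alpha, beta = bm.reference_rates("LD")["NIGHT"]
        assert 100 * alpha / (alpha + beta) == pytest.approx(30.0, rel=1e-9)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(bm.EstimationWarning):
            res = bm.TwoStateMarkov(make_seq("RRR")).fit()
        assert np.isnan(res.beta[DAY])
        assert np.isnan(res.alpha[NIGHT])
        assert res.alpha[DAY] == 0.0

    def test_average_activity_identity(self):
        res = bm.TwoStateMarkov(make_seq("RRAARAARRA", "DDDDDNNNNN")).fit()
        for ph in (DAY, NIGHT):
            act, rest = res.mean_activity_bout_min[ph], res.mean_rest_bout_min[ph]
            assert res.average_activity[ph] == pytest.approx(act / (act + rest))

    def test_summary_prints_parameters(self):
        res = bm.TwoStateMarkov(make_seq("RRAARA")).fit()
        text = res.summary()
        assert "alpha" in text and "DAY" in text
        assert "0.6667" in text

    def test_bout_permutation_invariance(self, rng):
        # permuting bout lengths within each state preserves the counts
        r_lens = rng.geometric(0.2, 30)
        a_lens = rng.geometric(0.4, 30)

        def build(rl, al):
            states = []
            for r, a in zip(rl, al):
                states.extend([REST] * r + [ACTIVE] * a)
            return bm.EncodedSequence("p", 10, states=states, phase=[DAY] * len(states))

        base = bm.count_transitions(build(r_lens, a_lens))
        perm = bm.count_transitions(build(rng.permutation(r_lens), rng.permutation(a_lens)))
        assert np.array_equal(base.table, perm.table)

    def test_consistency_long_run(self):
        # mean empirical non-truncated rest bout -> 1/alpha bins
        alpha, beta = 0.1, 0.3
        seq = bm.simulate_sequence(alpha, beta, np.zeros(10**6, np.uint8), seed=4)
        lengths = bm.bout_lengths(bm.extract_bouts(seq), state=REST)
        assert np.mean(lengths) == pytest.approx(1 / alpha, rel=0.02)


class TestGeometricPmf:
    def test_certain_exit(self):
        assert bm.geometric_bout_pmf(1.0, 1) == pytest.approx(1.0)
        assert bm.geometric_bout_pmf(1.0, 2) == pytest.approx(0.0)

    def test_halving(self):
        ks = np.array([1, 2, 3])
        np.testing.assert_allclose(bm.geometric_bout_pmf(0.5, ks), [0.5, 0.25, 0.125])

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.9])
    def test_normalization_and_mean(self, p):
        k = np.arange(1, 2000)
        pmf = bm.geometric_bout_pmf(p, k)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (k * pmf).sum() == pytest.approx(1 / p, abs=1e-6 / p)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            bm.geometric_bout_pmf(p, 1)


def test_results_simulate_roundtrip():
    """fit -> simulate -> refit recovers the parameters (self-consistency)."""
    phase = bm.ld_phase_track(2 * 8640, 24.0)
    seq = bm.simulate_sequence((0.04, 0.1), (0.3, 0.22), phase, seed=8)
    res = bm.TwoStateMarkov(seq).fit()
    sim = res.simulate(seed=9)
    res2 = bm.TwoStateMarkov(sim).fit()
    np.testing.assert_allclose(res2.alpha, res.alpha, rtol=0.2)
    assert sim.n_bins == seq.n_bins
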