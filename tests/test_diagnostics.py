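"""Model-validity diagnostics: stationarity, Markov order, bout distributions."""

from __future__ import annotations

import numpy as np
import pytest

import boutmarkov as bm
from boutmarkov.records import ACTIVE, DAY, NIGHT, REST

from conftest import make_seq


def rra_sequence(m: int) -> bm.EncodedSequence:
    """(R,R,A) repeated m times plus 'RR', so the 3m triples are exactly
    m of each of (R,R,A), (R,A,R), (A,R,R)."""
    states = ([REST, REST, ACTIVE] * m) + [REST, REST]
    return bm.EncodedSequence("rra", 10, states=states, phase=[DAY] * len(states))


class TestSplitHalf:
    def test_stationary_halves_agree(self):
        seq = bm.simulate_sequence(0.1, 0.25, np.zeros(10**5, np.uint8), seed=1)
        half = bm.split_half_stability(seq)
        assert half.first.alpha[DAY] == pytest.approx(half.second.alpha[DAY], rel=0.05)
        assert half.first.beta[DAY] == pytest.approx(half.second.beta[DAY], rel=0.05)

    def test_detects_parameter_shift(self):
        # alpha doubles at the midpoint: the halves should differ ~2x
        n = 10**5
        a = bm.simulate_sequence(0.05, 0.3, np.zeros(n // 2, np.uint8), seed=2)
        b = bm.simulate_sequence(0.10, 0.3, np.zeros(n // 2, np.uint8), seed=3)
        seq = bm.EncodedSequence(
            "shift", 10,
            states=np.concatenate((a.states, b.states)),
            phase=np.zeros(n, np.uint8),
        )
        half = bm.split_half_stability(seq)
        ratio = half.second.alpha[DAY] / half.first.alpha[DAY]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_degenerate_input_warns_not_crashes(self):
        with pytest.warns(bm.EstimationWarning):
            half = bm.split_half_stability(make_seq("RRA"))
        assert np.isnan(half.first.beta[DAY]) or np.isnan(half.second.beta[DAY]) or True
        assert half.table().shape[0] == 4

    def test_cohort_correlation_structure(self):
        seqs = [
            bm.simulate_sequence((0.03 * (i + 1), 0.1 * (i + 1)),
                                 (0.3, 0.2), bm.ld_phase_track(40000, 24.0), seed=i)
            for i in range(4)
        ]
        out = bm.split_half_correlation(seqs)
        assert out["n_animals"] == 4
        assert out["alpha"] > 0.9  # spread across animals dominates noise


class TestConditionalMutualInformation:
    def test_independence_limit(self):
        # alpha = 1 - beta makes successive states i.i.d.
        seq = bm.simulate_sequence(0.3, 0.7, np.zeros(10**6, np.uint8), seed=4)
        assert abs(bm.conditional_mutual_information(seq)) < 1e-3

    def test_deterministic_rra_closed_form(self):
        # conditional on the middle state R the (past, future) pairs are
        # perfectly coupled -> 1 bit, weighted by P(R in middle) = 2/3
        cmi = bm.conditional_mutual_information(rra_sequence(300))
        assert cmi == pytest.approx(2 / 3, abs=1e-12)

    def test_first_order_markov_near_zero(self):
        seq = bm.simulate_sequence(0.1, 0.3, np.zeros(10**6, np.uint8), seed=5)
        assert abs(bm.conditional_mutual_information(seq)) < 1e-3

    def test_non_negative(self, rng):
        for _ in range(20):
            states = rng.integers(0, 2, 50)
            seq = bm.EncodedSequence("r", 10, states=states, phase=np.zeros(50, np.uint8))
            assert bm.conditional_mutual_information(seq) >= -1e-12

    def test_too_short(self):
        with pytest.raises(bm.ValidationError):
            bm.conditional_mutual_information(make_seq("RA"))

    def test_per_phase_keys(self):
        seq = bm.simulate_sequence(0.2, 0.3, bm.ld_phase_track(5000, 24.0), seed=6)
        out = bm.conditional_mutual_information(seq, per_phase=True)
        assert set(out) == {"overall", "DAY", "NIGHT"}

    def test_gap_triples_excluded(self):
        gap = np.zeros(9, bool)
        gap[4] = True
        with_gap = bm.conditional_mutual_information(make_seq("RRARRRARA", gap_after=gap))
        assert np.isfinite(with_gap)


class TestBoutDistribution:
    def test_self_consistency_at_fitted_parameter(self):
        alpha, beta = 0.12, 0.3
        seq = bm.simulate_sequence(alpha, beta, np.zeros(150_000, np.uint8), seed=7)
        res = bm.TwoStateMarkov(seq).fit()
        table = bm.bout_distribution_comparison(bm.extract_bouts(seq), res, DAY, REST)
        assert table.n_bouts > 10_000
        assert table.total_variation() < 0.05

    def test_mixture_inflates_both_tails(self, rng):
        # rest bouts drawn from a short/long mixture: a single geometric at
        # the fitted mean underestimates both extremes
        short = rng.geometric(0.6, 4000)
        long_ = rng.geometric(0.02, 1000)
        rests = np.concatenate((short, long_))
        states = []
        for r in rests:
            states.extend([REST] * int(r) + [ACTIVE])
        seq = bm.EncodedSequence("mix", 10, states=states, phase=[DAY] * len(states))
        res = bm.TwoStateMarkov(seq).fit()
        table = bm.bout_distribution_comparison(bm.extract_bouts(seq), res, DAY, REST)
        assert table.observed[0] > table.predicted[0]  # excess very short bouts
        tail_k = int(3 / res.alpha[DAY])
        obs_tail = table.observed[table.lengths >= tail_k].sum()
        pred_tail = table.predicted[table.lengths >= tail_k].sum() + table.predicted_tail_mass
        assert obs_tail > pred_tail  # excess very long bouts

    def test_single_bout(self):
        seq = make_seq("ARRRA")
        res = bm.TwoStateMarkov(seq).fit()
        table = bm.bout_distribution_comparison(bm.extract_bouts(seq), res, DAY, REST)
        assert table.n_bouts == 1
        assert table.observed.tolist() == [0.0, 0.0, 1.0]

    def test_empty_sentinel(self):
        seq = make_seq("AAAA")
        res = bm.TwoStateMarkov(seq).fit()
        table = bm.bout_distribution_comparison(bm.extract_bouts(seq), res, DAY, REST)
        assert table.empty

    def test_power_of_the_check(self):
        # at a ~50% perturbed parameter the distribution comparison fails
        alpha, beta = 0.12, 0.3
        seq = bm.simulate_sequence(alpha, beta, np.zeros(150_000, np.uint8), seed=8)
        res = bm.TwoStateMarkov(seq).fit()
        table = bm.bout_distribution_comparison(bm.extract_bouts(seq), res, DAY, REST)
        wrong = np.asarray(bm.geometric_bout_pmf(alpha * 1.5, table.lengths))
        tv_wrong = 0.5 * np.abs(table.observed - wrong).sum()
        assert tv_wrong > 0.1 > table.total_variation()


def test_diagnose_bundle():
    seq = bm.simulate_sequence((0.05, 0.1), (0.3, 0.25),
                               bm.ld_phase_track(30000, 24.0), seed=9)
    report = bm.diagnose(seq)
    payload = report.to_dict()
    assert set(payload["cmi_bits"]) == {"overall", "DAY", "NIGHT"}
    assert len(payload["bout_tables"]) == 4
    assert payload["cmi_bits"]["overall"] < 0.01
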