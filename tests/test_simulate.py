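"""Generator correctness: determinism, stationarity, geometric dwell times."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import boutmarkov as bm
from boutmarkov.records import ACTIVE, DAY, NIGHT, REST


class TestSimulateSequence:
    def test_forced_alternation(self):
        seq = bm.simulate_sequence(1.0, 1.0, np.zeros(100, np.uint8), seed=0)
        assert (np.diff(seq.states.astype(int)) != 0).all()

    def test_absorbing_rest(self):
        seq = bm.simulate_sequence(0.0, 0.5, np.zeros(200, np.uint8), seed=0,
                                   initial_state="rest")
        assert (seq.states == REST).all()

    def test_stationary_fraction(self):
        seq = bm.simulate_sequence(0.5, 0.5, np.zeros(10**6, np.uint8), seed=1)
        assert np.mean(seq.states) == pytest.approx(0.5, abs=0.002)

    def test_seed_determinism(self):
        ph = bm.ld_phase_track(5000, 24.0)
        a = bm.simulate_sequence((0.1, 0.2), (0.3, 0.2), ph, seed=42)
        b = bm.simulate_sequence((0.1, 0.2), (0.3, 0.2), ph, seed=42)
        assert a == b

    def test_probability_domain_error(self):
        with pytest.raises(bm.ValidationError):
            bm.simulate_sequence(1.5, 0.5, np.zeros(10, np.uint8), seed=0)

    def test_phase_switched_rates(self):
        # day and night segments follow their own stationary fractions
        ph = bm.ld_phase_track(4 * 8640, 24.0)
        seq = bm.simulate_sequence((0.02, 0.2), (0.2, 0.02), ph, seed=3)
        day_act = seq.states[ph == DAY].mean()
        night_act = seq.states[ph == NIGHT].mean()
        assert day_act == pytest.approx(0.02 / 0.22, abs=0.02)
        assert night_act == pytest.approx(0.2 / 0.22, abs=0.02)

    def test_parameter_convergence(self):
        alpha, beta = 0.08, 0.25
        seq = bm.simulate_sequence(alpha, beta, np.zeros(10**6, np.uint8), seed=5)
        res = bm.TwoStateMarkov(seq).fit()
        assert res.alpha[DAY] == pytest.approx(alpha, rel=0.01)
        assert res.beta[DAY] == pytest.approx(beta, rel=0.01)

    def test_geometric_bout_law(self):
        # simulated non-truncated rest bouts pass a chi-square GOF test
        # against the generating geometric distribution
        alpha, beta = 0.1, 0.3
        n_bins = 200_000  # ~15k rest bouts
        seq = bm.simulate_sequence(alpha, beta, np.zeros(n_bins, np.uint8), seed=6)
        lengths = bm.bout_lengths(bm.extract_bouts(seq), state=REST)
        assert lengths.size > 10_000
        kmax = 40
        observed = np.bincount(np.minimum(lengths, kmax + 1))[1:]
        expected = np.append(
            bm.geometric_bout_pmf(alpha, np.arange(1, kmax + 1)),
            (1 - alpha) ** kmax,
        ) * lengths.size
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.01


class TestSimulateCohort:
    def test_zero_cv_shares_parameters(self):
        cfg = bm.default_config("LD24", n_animals=3, seed=1, record_days=4.5,
                               inter_animal_cv=0.0)
        sim = bm.simulate_cohort(cfg)
        assert sim.truths["alpha_day"].nunique() == 1
        assert sim.truths["alpha_day"].iloc[0] == pytest.approx(cfg.alpha_day)

    def test_bit_identical_under_same_config(self):
        cfg = bm.default_config("DD", n_animals=2, seed=9, record_days=5)
        s1 = bm.simulate_cohort(cfg)
        s2 = bm.simulate_cohort(cfg)
        for a, b in zip(s1.sequences, s2.sequences):
            assert a == b
        assert s1.truths.equals(s2.truths)

    def test_study_composition(self, study_cohort):
        counts = study_cohort.truths["condition"].value_counts()
        assert counts.to_dict() == {"LD24": 16, "DD": 16, "LD22": 8, "LD26": 8}
        assert len(study_cohort.sequences) == 48
        # every record satisfies the four-cycle inclusion rule
        for seq in study_cohort.sequences:
            assert seq.n_bins * seq.bin_seconds / 3600 >= 4 * 26

    def test_inclusion_rule_enforced(self):
        with pytest.raises(bm.ValidationError, match="four cycles"):
            bm.default_config("LD26", n_animals=2, seed=0, record_days=3.0)

    def test_dd_periods_near_24h(self):
        cfg = bm.default_config("DD", n_animals=8, seed=4, record_days=5)
        sim = bm.simulate_cohort(cfg)
        assert sim.truths["period_h"].between(22.5, 25).all()
        # subjective phase track follows the drawn period, not 24 h
        seq = sim.sequences[0]
        period_bins = int(round(sim.truths["period_h"][0] * 360))
        switches = np.flatnonzero(np.diff(seq.phase.astype(int)))
        assert abs(np.diff(switches).mean() - period_bins / 2) < 1

    def test_lognormal_draws_center_on_cohort_mean(self):
        cfg = bm.default_config("LD24", n_animals=400, seed=10, record_days=4.5)
        sim = bm.simulate_cohort(cfg)
        # arithmetic mean parameterization: draws average to the cohort mean
        assert sim.truths["alpha_day"].mean() == pytest.approx(cfg.alpha_day, rel=0.05)
        cv = sim.truths["alpha_day"].std() / sim.truths["alpha_day"].mean()
        assert cv == pytest.approx(0.2, rel=0.2)


class TestParameterRecovery:
    def test_per_animal_recovery(self):
        """Refitting each simulated animal recovers its own generating
        parameters; the cohort mean of fits matches the realized truth mean."""
        cfg = bm.default_config("LD24", n_animals=16, seed=12, record_days=7.0)
        sim = bm.simulate_cohort(cfg)
        fitted = []
        for seq, (_, truth) in zip(sim.sequences, sim.truths.iterrows()):
            res = bm.TwoStateMarkov(seq).fit()
            fitted.append(res.alpha[DAY])
            assert res.alpha[DAY] == pytest.approx(truth["alpha_day"], rel=0.12)
        true_rest_day = bm.mean_bout_min_from_prob(
            float(np.exp(np.log(sim.truths["alpha_day"]).mean()))
        )
        fit_rest_day = bm.mean_bout_min_from_prob(float(np.exp(np.log(fitted).mean())))
        assert fit_rest_day == pytest.approx(true_rest_day, rel=0.05)
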