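"""Shared fixtures: small hand-built sequences and one session-wide cohort."""

from __future__ import annotations

import numpy as np
import pytest

import boutmarkov as bm

#: Seed for the session-wide synthetic study; all cohort-level statistical
#: checks (rhythm screen, split-half correlation) run on this one dataset.
STUDY_SEED = 11


def make_seq(states: str, phases: str = None, gap_after=None, bin_seconds: int = 10,
             animal_id: str = "test", condition=None) -> bm.EncodedSequence:
    """Build an EncodedSequence from compact strings like 'RRAARA' / 'DDNNDD'."""
    s = [{"R": 0, "A": 1}[c] for c in states]
    if phases is None:
        p = [0] * len(s)
    else:
        p = [{"D": 0, "N": 1}[c] for c in phases]
    return bm.EncodedSequence(animal_id=animal_id, bin_seconds=bin_seconds,
                              states=s, phase=p, gap_after=gap_after,
                              condition=condition)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic study at the reference composition: 8/16/8 LD + 16 DD,
    one week per animal at 10-s bins, lognormal inter-animal cv 0.2."""
    return bm.simulate_study(seed=STUDY_SEED, record_days=7.0, inter_animal_cv=0.2)


@pytest.fixture(scope="session")
def study_fits(study_cohort):
    """Per-animal Markov fits for the session cohort."""
    return [bm.TwoStateMarkov(seq).fit() for seq in study_cohort.sequences]
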