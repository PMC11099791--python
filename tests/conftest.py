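"""Shared fixtures: desk-scale simulated cohorts and trained models.

The mechanism experiment uses 3 recordings per phenotype for training
(seeds 1-9) and 3 per phenotype held out for testing (seeds 11-19),
each one hour long and started at the default cohort phase where vagal
tone is high enough for exit block to be active.  The models are
trained once per session and shared by the classifier and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from exitblock.core import CLASS_ORDER, extract_triples
from exitblock.grid import train_grid
from exitblock.nn import train_nn
from exitblock.sim import DEFAULT_COHORT_START_MS, preset_for, simulate

HOUR_MS = 3.6e6

#: Experiment protocol: neural-network epochs (loss plateaus well before
#: this on the desk-scale training set).
NN_EPOCHS = 800


def seeded_cohort(seeds, duration_ms=HOUR_MS, start_time_ms=DEFAULT_COHORT_START_MS):
    """Three recordings per class, seeded explicitly in class order."""
    assert len(seeds) == 3 * len(CLASS_ORDER)
    cohort = []
    i = 0
    for diagnosis in CLASS_ORDER:
        params = preset_for(diagnosis)
        for _ in range(3):
            result = simulate(
                params, duration_ms, seed=seeds[i], start_time_ms=start_time_ms, label=diagnosis
            )
            cohort.append((result.series, diagnosis))
            i += 1
    return cohort


@pytest.fixture(scope="session")
def train_cohort():
    return seeded_cohort(list(range(1, 10)))


@pytest.fixture(scope="session")
def test_cohort():
    return seeded_cohort(list(range(11, 20)))


@pytest.fixture(scope="session")
def grid_model(train_cohort):
    return train_grid(train_cohort)


@pytest.fixture(scope="session")
def nn_model(train_cohort):
    triples, labels = [], []
    for series, label in train_cohort:
        t = extract_triples(series)
        triples.append(t)
        labels.extend([label] * t.shape[0])
    return train_nn(np.vstack(triples), labels, epochs=NN_EPOCHS, seed=0)


@pytest.fixture(scope="session")
def snd_hour():
    """One held-out hour of simulated sinus node dysfunction."""
    return simulate(
        preset_for(CLASS_ORDER[2]), HOUR_MS, seed=42, start_time_ms=DEFAULT_COHORT_START_MS
    ).series
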