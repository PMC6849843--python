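"""Shared fixtures: simulator snapshot series and pulse experiments.

The expensive session fixtures mirror the study conditions used by the
trend analyses: a 64 x 64 lattice, five grazing levels spanning the high
branch up to just below the upper fold, three replicate seeds.  Two
dispersal settings are used: the package default D = 0.1 for the
indicator trends, and D = 2 for the variogram (patch-size) experiment,
where the dispersal length sqrt(D/r) must exceed one cell for patch
structure to be resolvable at all.
"""

from __future__ import annotations

import numpy as np
import pytest

from sewscape import ModelParams, gradient_snapshots
from sewscape.recovery import recovery_experiment

GRADIENT_C = [5.0, 10.0, 15.0, 20.0, 24.0]
PULSE_C = [5.0, 10.0, 15.0, 20.0]
SEEDS = [0, 1, 2]


@pytest.fixture(scope="session")
def gradient_series_default():
    """Per-seed snapshot series at the default dispersal (D = 0.1)."""
    return {
        seed: gradient_snapshots(
            ModelParams(L=64, sigma=1.0, D=0.1, dt=0.01, seed=seed),
            GRADIENT_C,
            burn_in=100.0,
        )
        for seed in SEEDS
    }


@pytest.fixture(scope="session")
def gradient_series_dispersal():
    """Per-seed snapshot series with resolvable dispersal length (D = 2)."""
    return {
        seed: gradient_snapshots(
            ModelParams(L=64, sigma=1.0, D=2.0, dt=0.01, seed=seed),
            GRADIENT_C,
            burn_in=100.0,
        )
        for seed in SEEDS
    }


@pytest.fixture(scope="session")
def pulse_fits():
    """Recovery fits of the standard pulse experiment at four grazing levels."""
    params = ModelParams()
    return {
        c: recovery_experiment(params, c, delta_c=1.0, pulse_duration=1.0)
        for c in PULSE_C
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
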