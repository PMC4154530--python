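"""Shared fixtures: seeded epochs, small cohorts, and the LOSO comparison.

Everything is generated programmatically at test time; the heavyweight
10-subject LOSO comparison is computed once per session and shared by the
tests that assert on it.
"""

from __future__ import annotations

import numpy as np
import pytest

import somnoscore as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def recipes():
    return ss.default_recipes()


@pytest.fixture
def n2_epoch(rng, recipes):
    """A filtered synthetic N2 epoch (spindles/K-complexes possible)."""
    ep = ss.simulate_epoch(recipes[ss.SleepStage.N2], rng=rng)
    return ss.bandpass_filter(ep)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 40 epochs; enough for every stage to appear per fold."""
    cfg = ss.SimulationConfig(n_subjects=3, epochs_per_subject=40, seed=202)
    return ss.simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def loso_comparison():
    """The knowledge-vs-conventional LOSO comparison on a 10-subject cohort.

    100 epochs per subject keeps the five-stage mixture well represented in
    every training fold while the full two-pipeline comparison stays within
    an interactive runtime.
    """
    cfg = ss.SimulationConfig(n_subjects=10, epochs_per_subject=100, seed=11)
    cohort = ss.simulate_cohort(cfg)
    out = {}
    for mode in ("knowledge", "conventional"):
        ds = ss.cohort_to_dataset(cohort, feature_mode=mode)
        report = ss.loso_evaluate(
            ds, lambda: ss.SleepStageClassifier("rvm", ss.KernelSpec("linear"))
        )
        out[mode] = {
            "dataset": ds,
            "report": report,
            "separability": ss.feature_set_separability(ds),
        }
    return out
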