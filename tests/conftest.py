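"""Shared fixtures: memoized simulated populations.

Simulating and classifying a population is the expensive step, and many
tests interrogate the same (medium, condition) dataset, so populations are
built lazily once per session and cached.  Replicate random streams are
counter-based, so the first replicates of a 3-replicate run are identical
to a 2-replicate run with the same seed; tests that need exactly two
replicates subset by replicate_id.
"""

from __future__ import annotations

import pytest

from mmsurv.config import default_parameter_sets
from mmsurv.fates import ClassifierParams, Timeline, classify_population
from mmsurv.simulate import ground_truth_frame, simulate_condition

TEST_SEED = 1234

_CACHE: dict = {}


def _population(medium: str, condition: str, n: int, reps: int, **overrides):
    key = (medium, condition, n, reps, tuple(sorted(overrides.items())))
    if key not in _CACHE:
        cfg = default_parameter_sets()[medium].replace(
            n_lineages=n, n_replicates=reps, **overrides
        )
        timeline = Timeline.from_config(cfg)
        obs, truth = simulate_condition(cfg, condition, seed=TEST_SEED)
        fates, info = classify_population(obs, ClassifierParams(), timeline)
        _CACHE[key] = {
            "config": cfg,
            "timeline": timeline,
            "obs": obs,
            "truth": ground_truth_frame(truth),
            "fates": fates,
            "info": info,
        }
    return _CACHE[key]


@pytest.fixture(scope="session")
def population():
    """Factory fixture: population('glu-aa', 'CIP', n=500, reps=3)."""
    return _population


@pytest.fixture(scope="session")
def default_sets():
    return default_parameter_sets()
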