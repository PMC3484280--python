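"""Shared fixtures: default parameter sets and a cached default speed sweep."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from blmotion import (
    LGNParams,
    ShuntingParams,
    StimulusSpec,
    measure_run,
)
from blmotion.experiments import default_config, default_speed_grid

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    return StimulusSpec(), LGNParams(), ShuntingParams()


@dataclass
class SweepPoint:
    """Readout of one sweep speed plus trajectory activity extrema."""

    v_model: float
    readout: dict
    act_min: float
    act_max: float
    acc_min: float
    acc_max: float


@pytest.fixture(scope="session")
def default_sweep(defaults):
    """Full default speed sweep (60 log-spaced speeds over [1e-2, 1e2]),
    keeping per-run readouts and activity extrema but not the trajectories."""
    spec, lgn, p = defaults
    points = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for v in default_speed_grid(default_config().sweep):
            r, traj = measure_run(spec, lgn, p, v_model=float(v),
                                  return_trajectory=True)
            points.append(SweepPoint(
                v_model=float(v), readout=r.as_dict(),
                act_min=float(traj.states.min()),
                act_max=float(traj.states.max()),
                acc_min=float(traj.extra.min()),
                acc_max=float(traj.extra.max())))
    return points


@pytest.fixture(scope="session")
def v1_run(defaults):
    """The standard single run at unit model speed, with its trajectory."""
    spec, lgn, p = defaults
    return measure_run(spec, lgn, p, v_model=1.0, return_trajectory=True)
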