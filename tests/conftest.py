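"""Shared fixtures and helpers for the test suite.

Synthetic inputs are generated programmatically; heavier simulated datasets
are session-scoped so several tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import if2fret as f


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def noiseless_config(**overrides) -> f.SimulationConfig:
    """A deterministic-emission configuration: zero channel noise, zero
    substate/free width, no bleaching unless overridden."""
    base = dict(
        k_a=2.0, if2_conc=0.025, k_d=0.041, n_frames=600,
        substates=[f.Substate(mean=0.85, width=0.0, weight=1.0)],
        free_efret_width=0.0, noise_sd=0.0, kb_cy3=0.0, kb_cy5=0.0,
        bleedthrough=0.07,
    )
    base.update(overrides)
    return f.SimulationConfig(**base)


def make_efret_trajectory(efret, frame_time=0.1, trace_id="t", valid=None):
    """Wrap a raw E array into an EfretTrajectory."""
    efret = np.asarray(efret, float)
    if valid is None:
        valid = np.isfinite(efret)
    return f.EfretTrajectory(trace_id, frame_time, efret,
                             np.asarray(valid, bool), len(efret))


def make_path(macro, frame_time=0.1, trace_id="t", state_means=(0.0, 0.85)):
    """Build an IdealizedPath from a 0/1 macro label sequence."""
    macro = np.asarray(macro, bool)
    return f.IdealizedPath(trace_id, frame_time, macro.astype(np.int64),
                           macro, np.asarray(state_means, float),
                           np.ones(len(macro), bool))


def markov_efret_trace(rng, means, sds, stay, n_frames, start=0):
    """Synthetic E trajectory from a discrete-state Markov chain with
    Gaussian emissions; returns (efret, state_path)."""
    k = len(means)
    states = np.zeros(n_frames, dtype=int)
    s = start
    for t in range(n_frames):
        states[t] = s
        if rng.random() > stay:
            s = int(rng.choice([j for j in range(k) if j != s]))
    efret = rng.normal(np.asarray(means)[states], np.asarray(sds)[states])
    return efret, states


@pytest.fixture(scope="session")
def wt_scaled_result():
    """Full pipeline on the wild-type GTP condition at reduced trace count
    (3 replicates x 60 traces x 1800 frames); shared across tests."""
    cond = f.bundled_conditions()["wT"]
    return f.run_condition(cond, seed=20260921,
                           sim_overrides={"n_traces": 60},
                           mixture_components=1)
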