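"""Shared (mostly session-scoped) simulation fixtures.

The stochastic fixtures are deliberately desk-scale: short chains and
step counts chosen so the whole suite stays within a CI budget while the
assertions keep honest statistical margins.
"""

import numpy as np
import pytest

from nanopost.forcefield import DEFAULT_FF
from nanopost.md_engine import IntegratorConfig, integrate
from nanopost.polymer_model import build_initial_conformation, make_topology


@pytest.fixture(scope="session")
def free_flexible_traj():
    """Free flexible chain, Langevin NVT: bond-length and equipartition checks."""
    topo = make_topology(60, "flexible")
    state = build_initial_conformation(topo, velocity_init="maxwell",
                                       rng=np.random.default_rng(10))
    cfg = IntegratorConfig(n_equil=30_000, n_prod=200_000,
                           sample_interval=400, seed=11)
    return integrate(state, DEFAULT_FF, cfg)


@pytest.fixture(scope="session")
def free_semiflexible_frames():
    """Pooled free b=20 chains (equilibrium-WLC starts, low friction) for
    persistence fits; see the acceptance script for the protocol rationale."""
    topo = make_topology(120, "semiflexible")
    frames = []
    for s in range(30):
        state = build_initial_conformation(
            topo, conformation="wlc", rng=np.random.default_rng(1000 + s))
        cfg = IntegratorConfig(gamma=0.1, n_equil=20_000, n_prod=150_000,
                               sample_interval=300, seed=2000 + s)
        frames.append(integrate(state, DEFAULT_FF, cfg).frames)
    return np.concatenate(frames)


@pytest.fixture(scope="session")
def phantom_semiflexible_frames():
    """Phantom (no excluded volume) b=20 chains, frequently sampled."""
    topo = make_topology(100, "semiflexible")
    ff = DEFAULT_FF.phantom()
    frames = []
    for s in range(4):
        state = build_initial_conformation(
            topo, conformation="wlc", rng=np.random.default_rng(3000 + s))
        cfg = IntegratorConfig(n_equil=10_000, n_prod=300_000,
                               sample_interval=150, seed=4000 + s)
        frames.append(integrate(state, ff, cfg).frames)
    return np.concatenate(frames)
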