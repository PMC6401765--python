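"""NVT leap-frog molecular dynamics of one chain.

The integrator stores half-step velocities (velocity at t - dt/2 when the
positions are at t), mirroring the classic leap-frog scheme.  Sampled
kinetic energies are reported at on-step interpolated velocities.

Thermostats: Langevin (default; exact Ornstein-Uhlenbeck friction per
step) and Nose-Hoover (leap-frog variant with relaxation time tau), or
none for NVE checks.  Equilibrium averages are thermostat-independent,
which the test suite verifies rather than assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .array_geometry import NanopostArray, derive_geometry
from .forcefield import DEFAULT_FF, ForceFieldParams, raise_for_code
from .polymer_model import (
    ChainTopology,
    SimulationState,
    build_initial_conformation,
    make_topology,
)

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "MDError",
    "integrate",
    "run_experiment",
]

_THERMOSTATS = {"none": 0, "langevin": 1, "nose_hoover": 2}


class MDError(RuntimeError):
    """Integration failure; carries the offending step index."""

    def __init__(self, msg: str, step: int | None = None):
        super().__init__(msg)
        self.step = step


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration and sampling settings (reduced LJ units)."""

    dt: float = 0.005
    kT: float = 1.0
    thermostat: str = "langevin"
    gamma: float = 1.0          # Langevin friction, 1/tau
    tau_thermostat: float = 0.1  # Nose-Hoover relaxation time
    n_equil: int = 10_000
    n_prod: int = 100_000
    sample_interval: int = 500
    seed: int = 0
    store_velocities: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.kT <= 0:
            raise ValueError("dt and kT must be positive")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.thermostat not in _THERMOSTATS:
            raise ValueError(
                f"unknown thermostat {self.thermostat!r}; "
                f"choose from {sorted(_THERMOSTATS)}"
            )


@dataclass
class Trajectory:
    """Time-ordered production frames plus provenance metadata."""

    frames: np.ndarray          # (n_frames, N, 3)
    times: np.ndarray           # (n_frames,)
    potential: np.ndarray       # (n_frames,)
    kinetic: np.ndarray         # (n_frames,)
    topology: ChainTopology
    array: NanopostArray | None = None
    velocities: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    def __post_init__(self):
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")


def integrate(
    state: SimulationState,
    ff: ForceFieldParams = DEFAULT_FF,
    cfg: IntegratorConfig = IntegratorConfig(),
) -> Trajectory:
    """Propagate ``state`` (modified in place) and collect production frames.

    ``cfg.n_equil`` steps are discarded, then frames are sampled every
    ``cfg.sample_interval`` steps for ``cfg.n_prod`` steps.  Raises
    :class:`MDError` (with the failing step index) on bond overstretch or
    bead/post overlap; overstretch aborts rather than clamps.
    """
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    vel = np.ascontiguousarray(state.velocities, dtype=np.float64)
    N = pos.shape[0]
    angle_b = np.ascontiguousarray(state.topology.angle_b, dtype=np.float64)

    arr = state.array
    has_posts = arr is not None
    sp = arr.S_p if has_posts else 1.0
    dp_bare = max(arr.D_p, 0.0) if has_posts else 0.0
    thermo = _THERMOSTATS[cfg.thermostat]
    nb_mode = 1 if ff.nonbonded else 2

    _kernels._seed(cfg.seed % (2 ** 32))

    fbuf = np.zeros_like(pos)
    ref_pos = np.zeros_like(pos)
    chi = np.zeros(1)
    nstate = np.full(1, -1, dtype=np.int64)
    cap = max(80 * N, 1024)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    # separate buffers for _measure: it builds a skinless pair list and must
    # not clobber the cached Verlet list in pi/pj
    mi = np.empty(cap, dtype=np.int64)
    mj = np.empty(cap, dtype=np.int64)

    def advance(n_steps: int, done_before: int) -> None:
        nonlocal pi, pj, cap
        remaining = n_steps
        while remaining > 0:
            err, done = _kernels._advance(
                pos, vel, fbuf, angle_b, cfg.kT, ff.kappa, ff.R_o ** 2,
                nb_mode, has_posts, sp, dp_bare, cfg.dt, thermo,
                cfg.gamma, cfg.tau_thermostat, chi, remaining,
                pi, pj, ref_pos, nstate,
            )
            if err == _kernels.ERR_NLIST_OVERFLOW:
                cap *= 4
                pi = np.empty(cap, dtype=np.int64)
                pj = np.empty(cap, dtype=np.int64)
                nstate[0] = -1
                remaining -= done
                done_before += done
                continue
            if err != _kernels.ERR_NONE:
                step = done_before + done
                try:
                    raise_for_code(err, f"step {step}")
                except Exception as exc:
                    raise MDError(str(exc), step=step) from exc
            remaining -= done
            done_before += done

    def measure() -> tuple[float, float]:
        nonlocal mi, mj
        while True:
            pe, ke, err = _kernels._measure(
                pos, vel, fbuf, angle_b, cfg.kT, ff.kappa, ff.R_o ** 2,
                nb_mode, has_posts, sp, dp_bare, cfg.dt, mi, mj,
            )
            if err == _kernels.ERR_NLIST_OVERFLOW:
                mi = np.empty(4 * mi.shape[0], dtype=np.int64)
                mj = np.empty(4 * mj.shape[0], dtype=np.int64)
                continue
            raise_for_code(err, "measure")
            return pe, ke

    advance(cfg.n_equil, 0)

    n_samples = cfg.n_prod // cfg.sample_interval
    frames = np.empty((n_samples, N, 3))
    vels = np.empty((n_samples, N, 3)) if cfg.store_velocities else None
    times = np.empty(n_samples)
    pes = np.empty(n_samples)
    kes = np.empty(n_samples)
    t0 = state.time
    for s in range(n_samples):
        advance(cfg.sample_interval, cfg.n_equil + s * cfg.sample_interval)
        frames[s] = pos
        if vels is not None:
            vels[s] = vel
        times[s] = t0 + (cfg.n_equil + (s + 1) * cfg.sample_interval) * cfg.dt
        pes[s], kes[s] = measure()

    state.positions = pos
    state.velocities = vel
    state.time = t0 + (cfg.n_equil + n_samples * cfg.sample_interval) * cfg.dt

    return Trajectory(
        frames=frames, times=times, potential=pes, kinetic=kes,
        topology=state.topology, array=state.array, velocities=vels,
        metadata={
            "seed": cfg.seed,
            "dt": cfg.dt,
            "kT": cfg.kT,
            "thermostat": cfg.thermostat,
            "n_equil": cfg.n_equil,
            "n_prod": cfg.n_prod,
            "sample_interval": cfg.sample_interval,
        },
    )


def _replica_seeds(master_seed: int, n: int, salt: tuple = ()) -> list[int]:
    """Deterministic, order-independent per-replica seeds."""
    entropy = [int(master_seed)] + [int(x) for x in salt]
    ss = np.random.SeedSequence(entropy)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def run_experiment(config, orientation: str | None = None) -> list[Trajectory]:
    """Run the replicas described by a run configuration.

    ``config`` is an :class:`~nanopost.experiment_io.RunConfig` (or any
    object with the same attributes).  Replicas differ only by seed; the
    per-replica seeds are split deterministically from ``config.seed``, so
    reruns with the same config are bit-identical.
    """
    topo = make_topology(config.N, config.blocks, config.b)
    array = None
    if config.has_array:
        array = derive_geometry(config.S_p, D_p=config.D_p, d_p=config.d_p,
                                n_y=config.n_y, n_z=config.n_z)
    ori = orientation or config.orientation
    thermostat = config.thermostat
    if thermostat == "langevin":
        cfg_kw = {"gamma": config.gamma_or_tau}
    else:
        cfg_kw = {"tau_thermostat": config.gamma_or_tau}

    seeds = _replica_seeds(config.seed, config.replicas)
    trajectories = []
    for rep, seed in enumerate(seeds):
        state = build_initial_conformation(
            topo, array, orientation=ori,
            velocity_init="maxwell", kT=config.T,
            rng=np.random.default_rng(seed),
        )
        cfg = IntegratorConfig(
            dt=config.dt, kT=config.T, thermostat=thermostat,
            n_equil=config.n_equil, n_prod=config.n_prod,
            sample_interval=config.sample_interval, seed=seed, **cfg_kw,
        )
        traj = integrate(state, DEFAULT_FF, cfg)
        traj.metadata.update({"replica": rep, "orientation": ori,
                              "master_seed": config.seed})
        trajectories.append(traj)
    return trajectories
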