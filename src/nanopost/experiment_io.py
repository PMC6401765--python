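"""Run configuration, trajectory persistence, fixtures and sweep driver.

Configurations are YAML mappings with the keys
``N, blocks, b, S_p, D_p`` (or ``d_p``), ``n_y, n_z, dt, T, thermostat,
gamma_or_tau, n_equil, n_prod, sample_interval, seed, replicas,
orientation``.  Trajectories are stored as extended XYZ: the comment line
carries ``Properties=species:S:1:pos:R:3`` plus free key=value metadata
(time, array geometry, chain kind/stiffness), and the species column is
the per-bead block label (F/S).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .array_geometry import GeometryError, NanopostArray, derive_geometry
from .md_engine import Trajectory, run_experiment
from .observables import (
    axial_span,
    gyration_components,
    occupation_number,
)
from .polymer_model import ChainTopology, make_topology

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "write_trajectory",
    "read_trajectory",
    "Fixture",
    "make_fixture",
    "sweep",
    "summarize_trajectories",
    "write_manifest",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """A complete, reproducible description of one simulation experiment."""

    N: int = 100
    blocks: str = "flexible"        # flexible | semiflexible | diblock
    b: float = 20.0
    S_p: float | None = None
    D_p: float | None = None
    d_p: float | None = None
    n_y: int = 1
    n_z: int = 1
    dt: float = 0.005
    T: float = 1.0
    thermostat: str = "langevin"
    gamma_or_tau: float = 1.0
    n_equil: int = 10_000
    n_prod: int = 100_000
    sample_interval: int = 500
    seed: int = 0
    replicas: int = 1
    orientation: str = "parallel"

    @property
    def has_array(self) -> bool:
        return self.S_p is not None and (self.D_p is not None or self.d_p is not None)

    def derive_array(self) -> NanopostArray | None:
        if not self.has_array:
            return None
        return derive_geometry(self.S_p, D_p=self.D_p, d_p=self.d_p,
                               n_y=self.n_y, n_z=self.n_z)

    def to_dict(self) -> dict:
        return asdict(self)


_CONFIG_KEYS = set(RunConfig.__dataclass_fields__)


def load_config(source) -> RunConfig:
    """Parse a YAML run configuration from a path, file object or string."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a YAML mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "D_p" in data and "d_p" in data:
        raise ConfigError("specify only one of the keys 'D_p' and 'd_p'")
    try:
        cfg = RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    checks = {
        "N": cfg.N >= 2,
        "blocks": cfg.blocks in ("flexible", "semiflexible", "diblock"),
        "b": cfg.b >= 0,
        "dt": cfg.dt > 0,
        "T": cfg.T > 0,
        "thermostat": cfg.thermostat in ("langevin", "nose_hoover", "none"),
        "gamma_or_tau": cfg.gamma_or_tau > 0,
        "n_equil": cfg.n_equil >= 0,
        "n_prod": cfg.n_prod >= 1,
        "sample_interval": cfg.sample_interval >= 1,
        "replicas": cfg.replicas >= 1,
        "orientation": cfg.orientation in ("parallel", "perpendicular"),
    }
    bad = [k for k, ok in checks.items() if not ok]
    if bad:
        raise ConfigError(f"invalid configuration value(s) for: {bad}")
    if cfg.has_array:
        cfg.derive_array()  # raises GeometryError with the offending numbers


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(
        {k: v for k, v in cfg.to_dict().items() if v is not None},
        sort_keys=False,
    )
    if path is not None:
        Path(path).write_text(text)
    return text


# --------------------------------------------------------------------------
# extended-XYZ trajectory persistence
# --------------------------------------------------------------------------

_LABEL_CHARS = {0: "F", 1: "S"}


def _format_comment(meta: dict) -> str:
    parts = ["Properties=species:S:1:pos:R:3"]
    for key, value in meta.items():
        if isinstance(value, float):
            parts.append(f"{key}={float(value)!r}")
        else:
            parts.append(f"{key}={value}")
    return " ".join(parts)


def _parse_comment(line: str) -> dict:
    meta = {}
    for token in line.split():
        if "=" not in token:
            continue
        key, raw = token.split("=", 1)
        try:
            value = int(raw)
        except ValueError:
            try:
                value = float(raw)
            except ValueError:
                value = raw
        meta[key] = value
    return meta


def write_trajectory(traj: Trajectory, path) -> None:
    """Write production frames as concatenated extended-XYZ blocks."""
    topo = traj.topology
    species = [_LABEL_CHARS[int(l)] for l in topo.block_labels]
    base_meta = {"kind": topo.kind, "b_stiff": float(topo.b_stiff)}
    if traj.array is not None:
        a = traj.array
        base_meta.update({"S_p": a.S_p, "d_p": a.d_p, "n_y": a.n_y, "n_z": a.n_z})
    lines = []
    for f in range(traj.n_frames):
        meta = dict(base_meta, time=float(traj.times[f]))
        lines.append(str(topo.N))
        lines.append(_format_comment(meta))
        for i in range(topo.N):
            x, y, z = (float(v) for v in traj.frames[f, i])
            lines.append(f"{species[i]} {x!r} {y!r} {z!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`.

    Malformed input raises ``ConfigError`` naming the offending line.
    """
    text = Path(path).read_text().splitlines()
    frames, times, specs = [], [], None
    meta = {}
    i = 0
    nline = len(text)
    while i < nline:
        if not text[i].strip():
            i += 1
            continue
        try:
            natoms = int(text[i].strip())
        except ValueError:
            raise ConfigError(f"{path}: line {i + 1}: expected atom count, "
                              f"got {text[i]!r}")
        if i + 2 + natoms > nline:
            raise ConfigError(f"{path}: line {i + 1}: truncated frame "
                              f"(expected {natoms} atom lines)")
        meta = _parse_comment(text[i + 1])
        pos = np.empty((natoms, 3))
        spec = []
        for k in range(natoms):
            fields = text[i + 2 + k].split()
            if len(fields) != 4:
                raise ConfigError(f"{path}: line {i + 3 + k}: expected "
                                  f"'species x y z', got {text[i + 2 + k]!r}")
            spec.append(fields[0])
            pos[k] = [float(v) for v in fields[1:]]
        frames.append(pos)
        times.append(float(meta.get("time", len(times))))
        specs = spec
        i += 2 + natoms

    if not frames:
        topo = make_topology(2, "flexible")
        return Trajectory(frames=np.empty((0, 2, 3)), times=np.empty(0),
                          potential=np.empty(0), kinetic=np.empty(0),
                          topology=topo, metadata={})
    labels = np.array([0 if s == "F" else 1 for s in specs], dtype=np.int8)
    kind = str(meta.get("kind", "diblock" if 0 in labels and 1 in labels
                         else ("semiflexible" if labels[0] else "flexible")))
    topo = make_topology(len(labels), kind, float(meta.get("b_stiff", 20.0)))
    array = None
    if "S_p" in meta and "d_p" in meta:
        array = derive_geometry(meta["S_p"], d_p=meta["d_p"],
                                n_y=int(meta.get("n_y", 1)),
                                n_z=int(meta.get("n_z", 1)))
    n = len(frames)
    return Trajectory(
        frames=np.asarray(frames), times=np.asarray(times),
        potential=np.zeros(n), kinetic=np.zeros(n),
        topology=topo, array=array, metadata=dict(meta),
    )


# --------------------------------------------------------------------------
# analytic fixtures
# --------------------------------------------------------------------------

@dataclass
class Fixture:
    """A deterministic configuration with analytically known observables."""

    frames: np.ndarray
    expected: dict
    topology: ChainTopology | None = None
    array: NanopostArray | None = None


def make_fixture(kind: str, **params) -> Fixture:
    """Build a test configuration with its exact observable values attached.

    Kinds: ``rod`` (N, l), ``two_bead`` (r), ``cell_filling``
    (cells, S_p, d_p), ``wlc_correlated_bonds`` (P, l, n_bonds, seed).
    """
    if kind == "rod":
        N = int(params.get("N", 11))
        l = float(params.get("l", 0.97))
        pos = np.zeros((1, N, 3))
        pos[0, :, 0] = np.arange(N) * l
        # discrete rod: Rg^2 = l^2 (N^2 - 1)/12
        return Fixture(
            frames=pos,
            expected={
                "span": (N - 1) * l,
                "rg_parallel": math.sqrt(l * l * (N * N - 1) / 12.0),
                "rg_perp": 0.0,
            },
            topology=make_topology(N, "flexible"),
        )
    if kind == "two_bead":
        r = float(params.get("r", 1.0))
        pos = np.zeros((1, 2, 3))
        pos[0, 1, 0] = r

        def sq(q):
            q = np.asarray(q, dtype=float)
            return (1.0 + np.sinc(q * r / np.pi)) / 2.0

        return Fixture(frames=pos, expected={"sq": sq, "span": r})
    if kind == "cell_filling":
        cells = list(params["cells"])
        S_p = float(params.get("S_p", 12.0))
        d_p = float(params.get("d_p", 6.9))
        array = derive_geometry(S_p, d_p=d_p)
        pos = np.zeros((1, len(cells), 3))
        for k, (i, j) in enumerate(cells):
            pos[0, k, 1] = (i + 0.5) * S_p
            pos[0, k, 2] = (j + 0.5) * S_p
        return Fixture(frames=pos, array=array,
                       expected={"n": len(set(map(tuple, cells)))})
    if kind == "wlc_correlated_bonds":
        # freely rotating chains with the turn angle fixed at
        # cos(gamma) = exp(-l/P), so <u_i . u_{i+k}> = exp(-k l/P) exactly
        P = float(params.get("P", 19.0))
        l = float(params.get("l", 0.97))
        n_bonds = int(params.get("n_bonds", 400))
        n_frames = int(params.get("n_frames", 200))
        rng = np.random.default_rng(params.get("seed", 0))
        cos_g = math.exp(-l / P)
        sin_g = math.sqrt(1.0 - cos_g * cos_g)
        u = np.tile([1.0, 0.0, 0.0], (n_frames, 1))
        pos = np.zeros((n_frames, n_bonds + 1, 3))
        for k in range(n_bonds):
            if k > 0:
                helper = rng.normal(size=(n_frames, 3))
                e1 = np.cross(u, helper)
                e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
                e2 = np.cross(u, e1)
                phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_frames, 1))
                u = cos_g * u + sin_g * (np.cos(phi) * e1 + np.sin(phi) * e2)
                u /= np.linalg.norm(u, axis=1, keepdims=True)
            pos[:, k + 1] = pos[:, k] + l * u
        return Fixture(frames=pos, expected={"P": P, "bond_length": l})
    raise ValueError(f"unknown fixture kind {kind!r}")


# --------------------------------------------------------------------------
# sweep driver
# --------------------------------------------------------------------------

def summarize_trajectories(trajectories: list[Trajectory]) -> dict:
    """Observable summary (mean over replica means +- spread across replicas)."""
    topo = trajectories[0].topology
    array = trajectories[0].array
    subsets = {"": None}
    if topo.kind == "diblock":
        subsets["_flex"] = topo.block_beads("flexible")
        subsets["_semi"] = topo.block_beads("semiflexible")

    out: dict[str, float] = {}

    def aggregate(name, per_replica):
        vals = np.asarray(per_replica, dtype=float)
        out[name] = float(vals.mean())
        out[name + "_err"] = (
            float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        )

    for suffix, subset in subsets.items():
        aggregate("R_s" + suffix,
                  [axial_span(t.frames, subset).mean for t in trajectories])
        if array is not None:
            aggregate("n" + suffix,
                      [occupation_number(t.frames, array, subset).mean
                       for t in trajectories])
    gyr = [gyration_components(t.frames) for t in trajectories]
    out["Rg"] = float(np.mean([g.rg for g in gyr]))
    out["Rg_par"] = float(np.mean([g.rg_parallel for g in gyr]))
    out["Rg_perp"] = float(np.mean([g.rg_perp for g in gyr]))
    return out


def _row_seed(master: int, S_p: float, d_p: float) -> int:
    """Per-row seed from the master seed and the row geometry only, so row
    results do not depend on grid order."""
    ss = np.random.SeedSequence(
        [int(master), int(round(S_p * 1e6)), int(round(d_p * 1e6))]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def sweep(protocol: str, grid, base_config: RunConfig,
          outdir=None, log=None) -> pd.DataFrame:
    """Run one of the paper's two geometry-variation protocols.

    ``constant_Sp``: ``grid`` is a list of effective post diameters d_p at
    fixed S_p (taken from ``base_config``).  ``constant_w``: ``grid`` is a
    list of post spacings S_p at fixed passage width w (derived from
    ``base_config``'s geometry), with d_p = S_p - w per row.

    Infeasible rows are skipped (reason sent to ``log``).  Returns one row
    per geometry with the derived parameters and observable summary.
    """
    if protocol not in ("constant_Sp", "constant_w"):
        raise ValueError(f"unknown sweep protocol {protocol!r}")
    base_array = base_config.derive_array()
    if base_array is None:
        raise ConfigError("sweep needs a base configuration with array geometry")
    log = log or (lambda msg: None)

    rows = []
    for value in grid:
        if protocol == "constant_Sp":
            S_p, d_p = base_array.S_p, float(value)
        else:
            S_p = float(value)
            d_p = S_p - base_array.w
        try:
            array = derive_geometry(S_p, d_p=d_p,
                                    n_y=base_config.n_y, n_z=base_config.n_z)
        except GeometryError as exc:
            log(f"skipping S_p={S_p}, d_p={d_p}: {exc}")
            continue
        cfg = replace(base_config, S_p=S_p, d_p=d_p, D_p=None,
                      seed=_row_seed(base_config.seed, S_p, d_p))
        trajs = run_experiment(cfg)
        row = {
            "S_p": array.S_p, "d_p": array.d_p, "D_p": array.D_p,
            "w": array.w, "d_c": array.d_c, "F": array.F,
            "dc_over_w": array.confinement_ratio,
        }
        row.update(summarize_trajectories(trajs))
        rows.append((row, cfg, trajs))

    table = pd.DataFrame([r for r, _, _ in rows])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "sweep.csv", index=False)
        for row, cfg, trajs in rows:
            tag = f"Sp{row['S_p']:g}_dp{row['d_p']:g}"
            paths = []
            for rep, traj in enumerate(trajs):
                p = outdir / f"traj_{tag}_rep{rep}.xyz"
                write_trajectory(traj, p)
                paths.append(str(p))
            write_manifest(outdir / f"manifest_{tag}.json", cfg, trajs, paths)
    return table


def write_manifest(path, config: RunConfig, trajectories: list[Trajectory],
                   traj_paths: list[str] | None = None) -> dict:
    """Write a JSON manifest sufficient to reproduce the run bit-for-bit."""
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in config.to_dict().items() if v is not None},
        "seeds": [t.metadata.get("seed") for t in trajectories],
        "trajectories": traj_paths or [],
        "observables": summarize_trajectories(trajectories),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
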