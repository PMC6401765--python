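"""Potential-energy terms of the bead-spring chain and their forces.

Four contributions:

* purely repulsive WCA between beads (bonded pairs included), cut and
  shifted at 2^(1/6) sigma;
* the same WCA form between a bead and a post, evaluated at the distance
  to the post *surface* (axis distance minus D_p/2);
* FENE bond stretching with kappa = 30 eps/sigma^2, R_o = 1.5 sigma;
* bending U = (B/l)(1 + cos theta) per valence angle, with the prefactor
  frozen at B/l = b*kT (discretized-WLC convention), so a straight chain
  (theta = pi) costs nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from ._kernels import (
    ERR_NONE,
    ERR_OVERSTRETCH,
    ERR_PAIR_OVERLAP,
    ERR_POST_OVERLAP,
    RCUT,
)
from .polymer_model import SimulationState

__all__ = [
    "ForceFieldParams",
    "ForceFieldError",
    "OverlapError",
    "OverstretchError",
    "PostOverlapError",
    "wca_pair_energy",
    "post_energy",
    "fene_energy",
    "bending_energy",
    "total_energy_and_forces",
]


class ForceFieldError(RuntimeError):
    pass


class OverlapError(ForceFieldError):
    """Two beads at zero separation (divergent WCA)."""


class OverstretchError(ForceFieldError):
    """A bond at or beyond the FENE maximum extension R_o."""


class PostOverlapError(ForceFieldError):
    """A bead at or inside a bare post surface (divergent post WCA)."""


def raise_for_code(err: int, context: str = "") -> None:
    if err == ERR_NONE:
        return
    where = f" ({context})" if context else ""
    if err == ERR_OVERSTRETCH:
        raise OverstretchError(f"bond length >= R_o{where}")
    if err == ERR_POST_OVERLAP:
        raise PostOverlapError(f"bead at or inside a bare post{where}")
    if err == ERR_PAIR_OVERLAP:
        raise OverlapError(f"coincident beads{where}")
    raise ForceFieldError(f"kernel error code {err}{where}")


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants in reduced LJ units.

    ``nonbonded=False`` gives the phantom chain: WCA between non-adjacent
    beads is dropped (the chain can cross itself) while the bonded pair
    keeps its WCA+FENE bond, so the effective bond length stays ~0.97.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    kappa: float = 30.0
    R_o: float = 1.5
    bond_l: float = 0.97  # nominal bond length entering B/l = b*kT
    kT: float = 1.0
    nonbonded: bool = True

    @property
    def cutoff(self) -> float:
        return RCUT * self.sigma

    def __post_init__(self):
        if min(self.epsilon, self.sigma, self.kappa, self.R_o,
               self.bond_l, self.kT) <= 0:
            raise ValueError("force-field parameters must be strictly positive")

    def phantom(self) -> "ForceFieldParams":
        return replace(self, nonbonded=False)


DEFAULT_FF = ForceFieldParams()


def wca_pair_energy(r: float, epsilon: float = 1.0, sigma: float = 1.0) -> float:
    """Shifted WCA pair energy; exactly zero at and beyond 2^(1/6) sigma."""
    if r <= 0:
        raise OverlapError(f"divergent WCA overlap at r={r}")
    if r >= RCUT * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon


def post_energy(r_axis: float, D_p: float,
                epsilon: float = 1.0, sigma: float = 1.0) -> float:
    """Bead-post energy from one post: WCA at the surface distance r_axis - D_p/2."""
    s = r_axis - D_p / 2.0
    if s <= 0:
        raise PostOverlapError(
            f"bead at or inside post: axis distance {r_axis} <= D_p/2 = {D_p / 2}"
        )
    return wca_pair_energy(s, epsilon, sigma)


def fene_energy(l_ij: float, kappa: float = 30.0, R_o: float = 1.5) -> float:
    """FENE bond energy -(kappa/2) R_o^2 ln(1 - (l/R_o)^2); diverges at R_o."""
    if l_ij < 0:
        raise ValueError(f"bond length must be >= 0, got {l_ij}")
    if l_ij >= R_o:
        raise OverstretchError(f"bond overstretched: {l_ij} >= R_o = {R_o}")
    return -0.5 * kappa * R_o * R_o * math.log(1.0 - (l_ij / R_o) ** 2)


def bending_energy(theta: float, b: float, kT: float = 1.0) -> float:
    """Bending energy b*kT*(1 + cos theta); zero for a straight chain (theta = pi)."""
    if b < 0:
        raise ValueError(f"stiffness must be >= 0, got b={b}")
    return b * kT * (1.0 + math.cos(theta))


def _pair_buffers(N: int, factor: int = 80):
    cap = max(factor * N, 1024)
    return np.empty(cap, dtype=np.int64), np.empty(cap, dtype=np.int64)


def total_energy_and_forces(
    state: SimulationState, ff: ForceFieldParams = DEFAULT_FF
) -> tuple[float, np.ndarray]:
    """Total potential energy and exact negative-gradient forces.

    Sums nonbonded WCA over every pair within the cutoff (bonded pairs
    included), FENE over bonds, bending over angles, and the post term
    over the (at most four) nearest post images of each bead.
    """
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    N = pos.shape[0]
    f = np.zeros_like(pos)
    arr = state.array
    has_posts = arr is not None
    sp = arr.S_p if has_posts else 1.0
    dp_bare = max(arr.D_p, 0.0) if has_posts else 0.0

    nb_mode = 1 if ff.nonbonded else 2
    factor = 80
    while True:
        pi, pj = _pair_buffers(N, factor)
        npairs = 0
        if nb_mode == 1:
            npairs = _kernels._build_pairs(pos, _kernels.RCUT2, pi, pj)
            if npairs < 0:
                factor *= 4
                continue
        pe, err = _kernels._compute_forces(
            pos, f, state.topology.angle_b, ff.kT, ff.kappa, ff.R_o ** 2,
            nb_mode, npairs, pi, pj, has_posts, sp, dp_bare,
        )
        raise_for_code(err, "total_energy_and_forces")
        return float(pe), f
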