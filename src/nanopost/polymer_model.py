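"""Chain topology and initial-conformation construction.

The chain is a linear bead-spring polymer of ``N`` beads; each bead may
belong to a flexible block (bending stiffness b = 0) or a semi-flexible
block (b > 0, default 20).  A diblock splits at ``N // 2`` with the first
half flexible.  The junction bond is counted as flexible and an angle is
stiff only when both of its bonds lie in the semi-flexible block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .array_geometry import BEAD_SIZE, NanopostArray, min_distance_to_post_axis

__all__ = [
    "FLEXIBLE",
    "SEMIFLEXIBLE",
    "TopologyError",
    "PlacementError",
    "ChainTopology",
    "SimulationState",
    "make_topology",
    "build_initial_conformation",
]

FLEXIBLE = 0
SEMIFLEXIBLE = 1

#: FENE maximum bond extension; bonds at or above this length are invalid.
MAX_BOND = 1.5

#: Equilibrium effective bond length of the WCA+FENE bond.
DEFAULT_BOND = 0.97


class TopologyError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Raised when a straight initial chain cannot avoid bare-post overlap."""


@dataclass
class ChainTopology:
    """Beads, implicit consecutive bonds, and per-angle bending stiffness.

    ``angle_b[k]`` is the dimensionless stiffness b = B/(l kT) of the angle
    centered on bead ``k + 1`` (bonds ``k`` and ``k + 1``); there are
    ``N - 2`` angles and ``N - 1`` bonds.
    """

    N: int
    kind: str
    b_stiff: float
    block_labels: np.ndarray  # (N,) int8, FLEXIBLE or SEMIFLEXIBLE
    angle_b: np.ndarray       # (N-2,) float64

    @property
    def n_bonds(self) -> int:
        return self.N - 1

    @property
    def n_angles(self) -> int:
        return self.N - 2

    @property
    def bonds(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(self.N - 1)]

    @property
    def split_index(self) -> int | None:
        """First bead of the semi-flexible block (diblock only)."""
        return self.N // 2 if self.kind == "diblock" else None

    def block_beads(self, block: str) -> np.ndarray:
        """Bead indices of ``'flexible'``/``'semiflexible'`` beads (or ``'all'``)."""
        if block == "all":
            return np.arange(self.N)
        label = {"flexible": FLEXIBLE, "semiflexible": SEMIFLEXIBLE}[block]
        return np.nonzero(self.block_labels == label)[0]

    def to_dict(self) -> dict:
        return {
            "N": int(self.N),
            "kind": self.kind,
            "b_stiff": float(self.b_stiff),
            "block_labels": self.block_labels.tolist(),
            "angle_b": self.angle_b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainTopology":
        return cls(
            N=int(d["N"]),
            kind=str(d["kind"]),
            b_stiff=float(d["b_stiff"]),
            block_labels=np.asarray(d["block_labels"], dtype=np.int8),
            angle_b=np.asarray(d["angle_b"], dtype=np.float64),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChainTopology):
            return NotImplemented
        return (
            self.N == other.N
            and self.kind == other.kind
            and self.b_stiff == other.b_stiff
            and np.array_equal(self.block_labels, other.block_labels)
            and np.array_equal(self.angle_b, other.angle_b)
        )


def make_topology(N: int, kind: str, b_stiff: float = 20.0) -> ChainTopology:
    """Build a linear chain topology.

    Parameters
    ----------
    N : bead count (>= 2)
    kind : ``'flexible'``, ``'semiflexible'`` or ``'diblock'``
    b_stiff : dimensionless stiffness of semi-flexible angles (default 20)
    """
    if N < 2:
        raise TopologyError(f"need at least 2 beads, got N={N}")
    if b_stiff < 0:
        raise TopologyError(f"stiffness must be >= 0, got b={b_stiff}")
    if kind not in ("flexible", "semiflexible", "diblock"):
        raise TopologyError(f"unknown chain kind {kind!r}")

    labels = np.zeros(N, dtype=np.int8)
    angle_b = np.zeros(max(N - 2, 0), dtype=np.float64)
    if kind == "semiflexible":
        labels[:] = SEMIFLEXIBLE
        angle_b[:] = b_stiff
    elif kind == "diblock":
        half = N // 2
        labels[half:] = SEMIFLEXIBLE
        # angle k spans beads (k, k+1, k+2); stiff iff all three are in the
        # semi-flexible block, i.e. k >= half
        angle_b[half:] = b_stiff
    return ChainTopology(N=N, kind=kind, b_stiff=float(b_stiff),
                         block_labels=labels, angle_b=angle_b)


@dataclass
class SimulationState:
    """Positions/velocities of one chain, plus its topology and environment.

    Reduced LJ units throughout: lengths in sigma, energies in epsilon,
    mass m_o = 1, time in tau = sigma*sqrt(m_o/epsilon).
    """

    positions: np.ndarray   # (N, 3) float64
    velocities: np.ndarray  # (N, 3) float64
    topology: ChainTopology
    array: NanopostArray | None = None
    time: float = 0.0
    seed: int | None = None

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def validate(self) -> None:
        """Check the state invariants: finite bonds and no bead inside a bare post."""
        N = self.topology.N
        if self.positions.shape != (N, 3):
            raise ValueError(f"positions shape {self.positions.shape} != ({N}, 3)")
        lengths = self.bond_lengths()
        if lengths.size and lengths.max() >= MAX_BOND:
            k = int(np.argmax(lengths))
            raise ValueError(
                f"bond {k} overstretched: {lengths[k]:.4f} >= R_o = {MAX_BOND}"
            )
        if self.array is not None and self.array.D_p > 0:
            for i, p in enumerate(self.positions):
                d = min_distance_to_post_axis((p[1], p[2]), self.array)
                if d < self.array.D_p / 2:
                    raise ValueError(
                        f"bead {i} inside bare post: axis distance {d:.4f} < "
                        f"D_p/2 = {self.array.D_p / 2:.4f}"
                    )

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            topology=self.topology,
            array=self.array,
            time=self.time,
            seed=self.seed,
        )


def _sample_wlc_positions(topology: ChainTopology, bond0: float,
                          rng: np.random.Generator,
                          min_sep: float = 0.8, max_tries: int = 200) -> np.ndarray:
    """Random conformation with turn angles drawn from the bending Boltzmann
    weight exp(-b(1 - cos gamma)); resamples until no pair comes closer than
    ``min_sep`` (WCA-safe)."""
    N = topology.N
    for _ in range(max_tries):
        u = np.array([1.0, 0.0, 0.0])
        pos = np.zeros((N, 3))
        for k in range(N - 1):
            if k > 0:
                b = topology.angle_b[k - 1]
                x = rng.uniform()
                if b > 0:
                    cos_g = 1.0 + np.log(x + (1.0 - x) * np.exp(-2.0 * b)) / b
                else:
                    cos_g = 2.0 * x - 1.0
                cos_g = min(1.0, max(-1.0, cos_g))
                sin_g = np.sqrt(1.0 - cos_g * cos_g)
                helper = (np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9
                          else np.array([1.0, 0.0, 0.0]))
                e1 = np.cross(u, helper)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(u, e1)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                u = cos_g * u + sin_g * (np.cos(phi) * e1 + np.sin(phi) * e2)
                u /= np.linalg.norm(u)
            pos[k + 1] = pos[k] + bond0 * u
        from scipy.spatial.distance import pdist

        if pdist(pos).min() >= min_sep:
            return pos
    raise PlacementError(
        f"could not sample a self-avoiding WLC conformation in {max_tries} tries"
    )


def build_initial_conformation(
    topology: ChainTopology,
    array: NanopostArray | None = None,
    orientation: str = "parallel",
    bond0: float = DEFAULT_BOND,
    velocity_init: str = "zero",
    kT: float = 1.0,
    rng: np.random.Generator | None = None,
    cell: tuple[int, int] = (0, 0),
    conformation: str = "straight",
) -> SimulationState:
    """Place a completely straightened chain in (or without) the post array.

    ``parallel`` lays the chain along x on the center line of interstitial
    cell ``cell``; ``perpendicular`` lays it along y at the cell-center
    height z, threading passage apertures between posts.  For a free chain
    (``array=None``) the chain lies along x through the origin.

    ``conformation='wlc'`` (free chains only) instead draws the turn angles
    from the equilibrium bending Boltzmann distribution, which removes the
    slow orientational relaxation of a straightened start.
    """
    if not 0 < bond0 < MAX_BOND:
        raise ValueError(f"bond0 must be in (0, {MAX_BOND}), got {bond0}")
    N = topology.N
    x = np.arange(N) * bond0
    pos = np.zeros((N, 3))
    if conformation == "wlc":
        if array is not None:
            raise ValueError("conformation='wlc' is only supported for free chains")
        if rng is None:
            rng = np.random.default_rng()
        pos = _sample_wlc_positions(topology, bond0, rng)
    elif conformation != "straight":
        raise ValueError(f"unknown conformation {conformation!r}")
    elif array is None:
        pos[:, 0] = x
    else:
        cy = (cell[0] + 0.5) * array.S_p
        cz = (cell[1] + 0.5) * array.S_p
        if orientation == "parallel":
            pos[:, 0] = x
            pos[:, 1] = cy
            pos[:, 2] = cz
        elif orientation == "perpendicular":
            pos[:, 1] = cy + x - x[-1] / 2.0
            pos[:, 2] = cz
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        if array.D_p > 0:
            for i, p in enumerate(pos):
                d = min_distance_to_post_axis((p[1], p[2]), array)
                if d < array.D_p / 2:
                    raise PlacementError(
                        f"bead {i} overlaps a bare post (axis distance {d:.4f} < "
                        f"{array.D_p / 2:.4f}); chain cannot be placed"
                    )

    vel = np.zeros((N, 3))
    if velocity_init == "maxwell":
        if rng is None:
            rng = np.random.default_rng()
        vel = rng.normal(0.0, np.sqrt(kT), size=(N, 3))
        vel -= vel.mean(axis=0)  # zero total momentum
    elif velocity_init != "zero":
        raise ValueError(f"unknown velocity_init {velocity_init!r}")

    state = SimulationState(positions=pos, velocities=vel,
                            topology=topology, array=array)
    state.validate()
    return state
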