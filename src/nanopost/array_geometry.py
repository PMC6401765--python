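"""Square-lattice nanopost array geometry.

Posts are infinite cylinders parallel to the x axis, with axes at the
lattice points ``(i*S_p, j*S_p)`` in the y-z plane.  The interstitial
space among four neighbouring posts is a quasi-channel of effective
diameter ``d_c``; the gap between two nearest-neighbour posts is a
quasi-slit passage of width ``w``.  All lengths are in LJ sigma units.

Derived quantities::

    d_p = D_p + 0.9               effective post diameter
    w   = S_p - d_p               passage width
    d_c = sqrt(2)*S_p - d_p       effective interstitial channel diameter
    F   = pi*d_p**2 / (4*S_p**2)  post filling fraction

Interstitial cell centers sit at half-integer lattice points
``((i + 1/2)*S_p, (j + 1/2)*S_p)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BEAD_SIZE",
    "GeometryError",
    "NanopostArray",
    "derive_geometry",
    "cell_index",
    "cell_indices",
    "min_distance_to_post_axis",
]

#: Effective bead diameter added to the bare post diameter (sigma units).
BEAD_SIZE = 0.9


class GeometryError(ValueError):
    """Raised for infeasible post geometries (e.g. a closed passage)."""


@dataclass(frozen=True)
class NanopostArray:
    """A square lattice of parallel cylindrical posts and its derived
    confinement parameters.

    Use :func:`derive_geometry` to construct instances; the constructor
    itself does not re-derive the dependent fields.
    """

    S_p: float  #: post center-to-center spacing
    D_p: float  #: bare post diameter
    d_p: float  #: effective post diameter, D_p + 0.9
    w: float    #: passage width, S_p - d_p
    d_c: float  #: effective interstitial channel diameter, sqrt(2)*S_p - d_p
    F: float    #: post filling fraction, pi*d_p^2/(4*S_p^2)
    n_y: int = 1  #: lattice repeat count in y
    n_z: int = 1  #: lattice repeat count in z

    @property
    def confinement_ratio(self) -> float:
        """d_c / w — governs single vs multiple interstitial occupancy."""
        return self.d_c / self.w

    @property
    def period_y(self) -> float:
        return self.n_y * self.S_p

    @property
    def period_z(self) -> float:
        return self.n_z * self.S_p


def derive_geometry(
    S_p: float,
    D_p: float | None = None,
    *,
    d_p: float | None = None,
    n_y: int = 1,
    n_z: int = 1,
) -> NanopostArray:
    """Derive all confinement parameters from the post spacing and diameter.

    Exactly one of ``D_p`` (bare diameter) or ``d_p`` (effective diameter,
    already including the bead size) must be given.

    Raises
    ------
    GeometryError
        If ``S_p <= 0``, the diameter is negative, or the passage closes
        (``w <= 0``).
    """
    if S_p <= 0:
        raise GeometryError(f"post spacing must be positive, got S_p={S_p}")
    if (D_p is None) == (d_p is None):
        raise GeometryError("specify exactly one of D_p or d_p")
    if d_p is None:
        if D_p < 0:
            raise GeometryError(f"bare post diameter must be >= 0, got D_p={D_p}")
        d_p = D_p + BEAD_SIZE
    else:
        if d_p < 0:
            raise GeometryError(f"effective post diameter must be >= 0, got d_p={d_p}")
        D_p = d_p - BEAD_SIZE  # may be negative for d_p < 0.9 (zero-size limit)
    w = S_p - d_p
    if w <= 0:
        raise GeometryError(
            f"passage closed: w = S_p - d_p = {w:g} <= 0 (S_p={S_p}, d_p={d_p})"
        )
    d_c = math.sqrt(2.0) * S_p - d_p
    F = math.pi * d_p * d_p / (4.0 * S_p * S_p)
    if n_y < 1 or n_z < 1:
        raise GeometryError("lattice repeat counts must be >= 1")
    return NanopostArray(
        S_p=float(S_p), D_p=float(D_p), d_p=float(d_p),
        w=float(w), d_c=float(d_c), F=float(F), n_y=int(n_y), n_z=int(n_z),
    )


def cell_index(point, array: NanopostArray) -> tuple[int, int]:
    """Map a y-z point to the interstitial cell whose center is nearest.

    Cell ``(i, j)`` is centered at ``((i + 1/2)*S_p, (j + 1/2)*S_p)``.
    Points exactly on a cell boundary (a passage midline) are assigned to
    the lexicographically smallest adjacent label, so the mapping is
    deterministic.
    """
    y, z = float(point[0]), float(point[1])
    S = array.S_p
    return _axis_cell(y, S), _axis_cell(z, S)


def _axis_cell(u: float, S: float) -> int:
    q = u / S
    f = math.floor(q)
    if q == f:  # on a boundary: tie between cells f-1 and f -> smaller wins
        return int(f) - 1
    return int(f)


def min_distance_to_post_axis(point, array: NanopostArray) -> float:
    """Euclidean y-z distance from a point to the nearest post axis.

    Uses the periodic lattice image convention, so the result never
    exceeds ``S_p / sqrt(2)`` (the half-diagonal of a lattice cell).
    """
    y, z = float(point[0]), float(point[1])
    S = array.S_p
    u = y - S * math.floor(y / S)
    v = z - S * math.floor(z / S)
    du = min(u, S - u)
    dv = min(v, S - v)
    return math.hypot(du, dv)


def cell_indices(points: np.ndarray, array: NanopostArray) -> np.ndarray:
    """Vectorized :func:`cell_index` for an (M, 2) array of y-z points."""
    pts = np.asarray(points, dtype=float)
    q = pts / array.S_p
    f = np.floor(q)
    on_edge = q == f
    idx = f.astype(np.int64)
    idx[on_edge] -= 1
    return idx
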