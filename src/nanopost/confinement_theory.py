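"""Confinement free energies and predicted penetration transitions.

An interstitial volume is approximated as a square channel of width d_c
and a passage aperture as a slit of height w (half the free-energy
penalty of a square channel of the same size).  Equating the channel and
slit penalties yields the confinement ratio d_c/w at which a chain first
spreads from a single interstitial volume into several:

* semi-flexible chain (Odijk slit vs de Gennes channel):
  d_c/w = 2.165 (P/w)^(2/5) (a/w)^(1/5)
* flexible chain (de Gennes on both sides; all parameters cancel):
  d_c/w = 2^(3/5) = 1.52
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TheoryParams",
    "NoTransitionError",
    "odijk_channel_free_energy",
    "degennes_channel_free_energy",
    "slit_free_energy",
    "semiflexible_transition_ratio",
    "semiflexible_transition_ratio_numeric",
    "flexible_transition_ratio",
    "flexible_transition_ratio_numeric",
    "detect_transition",
    "detect_transition_table",
]

ODIJK_PREFACTOR = 2.2072
DEGENNES_PREFACTOR = 4.0
SEMIFLEXIBLE_TRANSITION_PREFACTOR = 2.165


class NoTransitionError(RuntimeError):
    """The occupation curve never exceeds the transition threshold."""


@dataclass(frozen=True)
class TheoryParams:
    """Inputs to the free-energy predictions (sigma units)."""

    L: float            # contour length
    P: float = 19.23    # persistence length (measured for b = 20)
    a: float = 0.97     # monomer size = effective bond length
    w: float = 2.0      # passage width
    d_c: float | None = None

    def __post_init__(self):
        for name in ("L", "P", "a", "w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def odijk_channel_free_energy(L: float, P: float, D: float) -> float:
    """Strong-confinement (deflection-segment) penalty in a square channel:
    dA/kT = 2.2072 L P^(-1/3) D^(-2/3).  Valid for D <~ P (caller's duty)."""
    _check_positive(L=L, P=P, D=D)
    return ODIJK_PREFACTOR * L * P ** (-1.0 / 3.0) * D ** (-2.0 / 3.0)


def degennes_channel_free_energy(L: float, P: float, a: float, D: float) -> float:
    """Moderate-confinement (blob) penalty in a square channel:
    dA/kT = 4.0 L (P a)^(1/3) D^(-5/3)."""
    _check_positive(L=L, P=P, a=a, D=D)
    return DEGENNES_PREFACTOR * L * (P * a) ** (1.0 / 3.0) * D ** (-5.0 / 3.0)


def slit_free_energy(channel_value: float) -> float:
    """Slit penalty: half the square-channel penalty at the same width."""
    return channel_value / 2.0


def semiflexible_transition_ratio(P: float, w: float, a: float) -> float:
    """Closed-form d_c/w at the semi-flexible penetration transition:
    2.165 (P/w)^(2/5) (a/w)^(1/5)."""
    _check_positive(P=P, w=w, a=a)
    return (SEMIFLEXIBLE_TRANSITION_PREFACTOR
            * (P / w) ** 0.4 * (a / w) ** 0.2)


def semiflexible_transition_ratio_numeric(P: float, w: float, a: float,
                                          L: float = 1.0) -> float:
    """d_c/w from the equal-free-energy condition solved numerically:
    Odijk slit at w == de Gennes channel at d_c.  Independent check on the
    closed form (agreement limited by the rounding of the 2.165 prefactor)."""
    _check_positive(P=P, w=w, a=a, L=L)
    target = slit_free_energy(odijk_channel_free_energy(L, P, w))

    def residual(d_c):
        return degennes_channel_free_energy(L, P, a, d_c) - target

    lo, hi = 1e-6 * w, 1e6 * w
    return brentq(residual, lo, hi, xtol=1e-12, rtol=1e-14) / w


def flexible_transition_ratio() -> float:
    """d_c/w at the flexible-chain penetration transition: 2^(3/5) = 1.52.

    All L, P, a dependence cancels when de Gennes applies on both sides."""
    return 2.0 ** 0.6


def flexible_transition_ratio_numeric(P: float = 19.23, w: float = 2.0,
                                      a: float = 0.97, L: float = 1.0) -> float:
    """Root of degennes(d_c) = degennes(w)/2; must not depend on P, a, L."""
    _check_positive(P=P, w=w, a=a, L=L)
    target = slit_free_energy(degennes_channel_free_energy(L, P, a, w))

    def residual(d_c):
        return degennes_channel_free_energy(L, P, a, d_c) - target

    return brentq(residual, 1e-6 * w, 1e6 * w, xtol=1e-12, rtol=1e-14) / w


def detect_transition(coords, n, threshold: float = 1.05) -> float:
    """Coordinate at which the mean occupation number first exceeds
    ``threshold`` (default 1 + 0.05), by linear interpolation.

    The curve is sorted by ``coords`` and auto-oriented so that ``n``
    increases along the scan direction; the returned value is in the
    original coordinate.  Raises :class:`NoTransitionError` if the curve
    never exceeds the threshold, and ``ValueError`` if it starts above it
    (no single-occupancy branch to interpolate from).
    """
    c = np.asarray(coords, dtype=float)
    v = np.asarray(n, dtype=float)
    if c.shape != v.shape or c.size < 2:
        raise ValueError("need matching coordinate/occupation arrays of size >= 2")
    order = np.argsort(c)
    c, v = c[order], v[order]
    if v[0] > v[-1]:  # occupation grows toward smaller coordinates
        c, v = c[::-1], v[::-1]
    if v.max() <= threshold:
        raise NoTransitionError(
            f"occupation never exceeds threshold {threshold}")
    above = np.nonzero(v > threshold)[0]
    k = int(above[0])
    if k == 0:
        raise ValueError("curve already above threshold at the first point")
    frac = (threshold - v[k - 1]) / (v[k] - v[k - 1])
    return float(c[k - 1] + frac * (c[k] - c[k - 1]))


def detect_transition_table(table, n_column: str = "n",
                            threshold: float = 1.05) -> dict:
    """Penetration transition of a sweep table, in both coordinates.

    ``table`` must provide columns ``F``, ``dc_over_w`` and ``n_column``
    (a pandas DataFrame or dict of arrays).  Returns
    ``{"F": ..., "dc_over_w": ...}``.
    """
    return {
        "F": detect_transition(np.asarray(table["F"], dtype=float),
                               np.asarray(table[n_column], dtype=float),
                               threshold),
        "dc_over_w": detect_transition(
            np.asarray(table["dc_over_w"], dtype=float),
            np.asarray(table[n_column], dtype=float), threshold),
    }
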