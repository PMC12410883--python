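"""Conduction-velocity and internode-length models for myelinated fibers.

The conduction velocity of a myelinated axon is estimated from its inner
(axon) diameter ``d``, its outer fiber diameter ``D`` and the g-ratio
``g = d / D`` via the generalized Rushton relation

    v = s * d * (-ln g)**alpha,        d = g * D

where ``s`` is an absolute scaling factor in inverse microseconds and
``alpha`` is a dimensionless exponent. The classical cable-equation
derivation gives ``alpha = 0.5``; simulation-calibrated work places it at
0.68; reversing Rushton's optimal-g argument gives ``alpha = -ln(g)`` for a
population whose observed mean g-ratio is assumed optimal. Because
``µm * µs⁻¹ = m/s``, feeding diameters in micrometres and ``s`` in µs⁻¹
yields velocities directly in metres per second.

The internode length obeys the companion relation ``L ∝ d * (-ln g)**0.5``,
which is maximal at ``g = e**-0.5``; more generally ``g * (-ln g)**alpha``
peaks at ``g = e**-alpha``, making :func:`derive_alpha` and
:func:`optimal_g` mutual inverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VelocityModel",
    "conduction_velocity",
    "derive_alpha",
    "velocity_ratio",
    "travel_time",
    "internode_length_relative",
    "optimal_g",
]

#: Absolute scaling factor calibrated against biophysical simulation, µs⁻¹.
DEFAULT_SCALING_S = 7.5
#: Simulation-optimized exponent of the generalized Rushton relation.
DEFAULT_ALPHA = 0.68


@dataclass(frozen=True)
class VelocityModel:
    """Parameters of the scaled generalized Rushton velocity relation.

    Attributes
    ----------
    scaling_s : float
        Absolute scale ``s`` in µs⁻¹ converting relative velocities into
        m/s when diameters are given in µm.
    alpha : float
        Exponent on ``-ln g``; must lie in ``(0, 1]``.
    """

    scaling_s: float = DEFAULT_SCALING_S
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.scaling_s <= 0:
            raise ValueError(f"scaling_s must be positive, got {self.scaling_s}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


def _check_g(g) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if np.any((g <= 0) | (g >= 1)):
        raise ValueError("g-ratio must lie strictly inside (0, 1)")
    return g


def conduction_velocity(outer_diameter_um, g_ratio, model: VelocityModel | None = None):
    """Conduction velocity in m/s for outer diameter ``D`` (µm) and g-ratio.

    Evaluates ``v = s * (g * D) * (-ln g)**alpha``. Accepts scalars or
    arrays (broadcast); returns the same shape.
    """
    model = model or VelocityModel()
    g = _check_g(g_ratio)
    D = np.asarray(outer_diameter_um, dtype=float)
    if np.any(D <= 0):
        raise ValueError("outer diameter must be positive")
    v = model.scaling_s * (g * D) * (-np.log(g)) ** model.alpha
    return float(v) if v.ndim == 0 else v


def derive_alpha(g_ratio: float) -> float:
    """Exponent alpha obtained by treating the observed mean g as optimal.

    Reverses the optimal-g argument: if ``g*(-ln g)**alpha`` is maximal at
    the observed g, then ``alpha = -ln(g)``.
    """
    g = float(g_ratio)
    if not 0 < g < 1:
        raise ValueError(f"g-ratio must lie in (0, 1), got {g}")
    return -math.log(g)


def velocity_ratio(g_ratio: float, alpha_a: float, alpha_b: float) -> float:
    """Percent velocity change when exponent ``alpha_b`` is replaced by ``alpha_a``.

    Returns ``100 * ((-ln g)**alpha_a / (-ln g)**alpha_b - 1)``; diameter and
    scale cancel, so only the exponent matters.
    """
    g = float(_check_g(g_ratio))
    neg_log_g = -math.log(g)
    return 100.0 * (neg_log_g**alpha_a / neg_log_g**alpha_b - 1.0)


def travel_time(path_length_m: float, velocity_mps: float) -> float:
    """Signal travel time in milliseconds over ``path_length_m`` metres."""
    if path_length_m <= 0 or velocity_mps <= 0:
        raise ValueError("path length and velocity must be positive")
    return 1000.0 * path_length_m / velocity_mps


def internode_length_relative(outer_diameter_um, g_ratio):
    """Relative internode length ``d * (-ln g)**0.5`` with ``d = g*D`` (µm).

    Proportional scale only — no absolute calibration is claimed.
    """
    g = _check_g(g_ratio)
    D = np.asarray(outer_diameter_um, dtype=float)
    if np.any(D <= 0):
        raise ValueError("outer diameter must be positive")
    L = (g * D) * np.sqrt(-np.log(g))
    return float(L) if L.ndim == 0 else L


def optimal_g(alpha: float) -> float:
    """The g-ratio maximizing ``g * (-ln g)**alpha``, namely ``e**-alpha``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return math.exp(-alpha)
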