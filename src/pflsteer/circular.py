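"""Angular conventions and circular statistics.

All angles in this package are in degrees, wrapped to the half-open interval
(-180, +180].  The behavioral convention is: 0 deg = the fly directly faces
the visual cue, positive angles = clockwise.  Radians appear only transiently
inside trigonometric calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RHO_UNDEFINED_TOL",
    "CircularSummary",
    "wrap_deg",
    "circ_mean",
    "circ_consistency",
    "circ_dist_signed",
    "circ_summary",
]

#: Below this mean resultant length the mean direction is treated as undefined.
RHO_UNDEFINED_TOL = 1e-9


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean direction and consistency of a sample of angles.

    ``mean_direction`` is the circular mean in degrees, wrapped to
    (-180, 180]; ``consistency`` is the mean resultant length rho in [0, 1]
    (1 = all angles identical, 0 = angles uniformly spread).  When rho is
    numerically zero the mean direction is arbitrary and ``mean_defined``
    is False.
    """

    mean_direction: float
    consistency: float
    n: int
    mean_defined: bool


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def wrap_deg(x):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180].

    Accepts scalars or arrays.  Raises ``ValueError`` on non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    _check_finite(arr, "angle")
    # map to [-180, 180) then move -180 to +180 to get (-180, 180]
    wrapped = np.mod(arr + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(x) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def _resultant(thetas) -> tuple[float, float, int]:
    arr = np.asarray(thetas, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty angle list")
    _check_finite(arr, "angles")
    rad = np.deg2rad(arr)
    return float(np.sum(np.cos(rad))), float(np.sum(np.sin(rad))), int(arr.size)


def circ_mean(thetas) -> float:
    """Circular mean of angles in degrees (two-argument arctangent of the
    summed unit vectors), wrapped to (-180, 180].

    Raises ``ValueError`` for an empty input or when the resultant length is
    numerically zero (mean undefined).
    """
    c, s, n = _resultant(thetas)
    if np.hypot(c, s) / n < RHO_UNDEFINED_TOL:
        raise ValueError("circular mean undefined: resultant length ~ 0")
    return wrap_deg(np.rad2deg(np.arctan2(s, c)))


def circ_consistency(thetas) -> float:
    """Mean resultant length rho in [0, 1] of angles in degrees.

    rho = 1 indicates a constant direction; rho = 0 indicates uniform
    sampling of all directions.
    """
    c, s, n = _resultant(thetas)
    return min(1.0, float(np.hypot(c / n, s / n)))


def circ_summary(thetas) -> CircularSummary:
    """Joint circular mean + consistency with an explicit undefined-mean flag."""
    c, s, n = _resultant(thetas)
    rho = min(1.0, float(np.hypot(c / n, s / n)))
    defined = rho >= RHO_UNDEFINED_TOL
    mean = wrap_deg(np.rad2deg(np.arctan2(s, c))) if defined else float("nan")
    return CircularSummary(mean_direction=mean, consistency=rho, n=n, mean_defined=defined)


def circ_dist_signed(a, b):
    """Signed shortest-arc angular difference wrap(a - b) in (-180, 180].

    Positive = ``a`` is clockwise of ``b``.  ``abs`` of the result is the
    angular (great-circle) distance.  Accepts scalars or arrays.
    """
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) \
        if not (np.isscalar(a) and np.isscalar(b)) else wrap_deg(float(a) - float(b))
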