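"""Closed-form reference results for kappa^2 in limiting cases.

Two classical results anchor the Monte-Carlo engines:

* the probability density of kappa^2 when both dipoles are isotropically
  oriented, whose mean is the familiar dynamic-isotropic value 2/3;
* the Knoester-van Himbergen average for planar systems of identically
  oriented donors and acceptors at fixed tilt theta from the membrane
  normal,

      <kappa^2> = 2/3 - (2/3) S + S^2,    S = P2(cos(theta)) = (3 cos^2(theta) - 1)/2,

  which runs from 5/9 (at theta = 41.81 deg and its mirror) to 1.25 (at
  90 deg) and crosses the isotropic value 2/3 at four tilts.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "isotropic_pdf",
    "isotropic_mean",
    "order_parameter",
    "knoester_mean",
    "knoester_special_angles",
]

_LN_2_SQRT3 = math.log(2.0 + math.sqrt(3.0))
_TWO_SQRT3 = 2.0 * math.sqrt(3.0)

#: exact mean of kappa^2 over the isotropic density
isotropic_mean = 2.0 / 3.0


def isotropic_pdf(kappa2):
    """Probability density of kappa^2 for isotropically oriented dipoles.

    Piecewise over its support (0, 4] (integrable singularity at 0):

        p = ln(2 + sqrt(3)) / (2 sqrt(3) sqrt(k2))                         0 < k2 <= 1
        p = ln((2 + sqrt(3)) / (sqrt(k2) + sqrt(k2 - 1))) / (2 sqrt(3) sqrt(k2))   1 <= k2 <= 4

    Accepts scalars or arrays; raises on arguments outside (0, 4].
    """
    arr = np.asarray(kappa2, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 4.0):
        raise ValueError("kappa2 outside the density's domain (0, 4]")
    s = np.sqrt(arr)
    num = np.full_like(arr, _LN_2_SQRT3)
    upper = arr > 1.0
    if np.any(upper):
        su = s[upper]
        num[upper] = np.log((2.0 + math.sqrt(3.0)) / (su + np.sqrt(arr[upper] - 1.0)))
    out = num / (_TWO_SQRT3 * s)
    return float(out) if np.isscalar(kappa2) else out


def order_parameter(theta_deg: float) -> float:
    """Second-rank order parameter S = P2(cos(theta)) for a fixed tilt."""
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError(f"theta_deg={theta_deg!r} outside [0, 180]")
    c = math.cos(math.radians(theta_deg))
    return (3.0 * c * c - 1.0) / 2.0


def knoester_mean(theta_deg: float) -> float:
    """<kappa^2> for coplanar, identically oriented dipoles at fixed tilt.

    Valid for planar donor/acceptor distributions with no orientational
    heterogeneity (sigma = 0), where <cos^2 theta> = cos^2 theta.
    """
    s = order_parameter(theta_deg)
    return 2.0 / 3.0 - (2.0 / 3.0) * s + s * s


def knoester_special_angles() -> list[tuple[float, float]]:
    """Stationary and isotropic-crossing tilts of the Knoester curve.

    Returns (theta_deg, <kappa^2>) pairs: the local extrema at 0, 90 and
    180 deg and at the minima acos(sqrt(5/9)) and its mirror, plus the four
    tilts where the average equals 2/3 (S = 0: the magic angle and its
    mirror; S = 2/3: acos(sqrt(7/9)) and its mirror).
    """
    t_min = math.degrees(math.acos(math.sqrt(5.0 / 9.0)))
    t_magic = math.degrees(math.acos(math.sqrt(1.0 / 3.0)))
    t_s23 = math.degrees(math.acos(math.sqrt(7.0 / 9.0)))
    angles = [
        0.0,
        t_s23, t_min, t_magic,
        90.0,
        180.0 - t_magic, 180.0 - t_min, 180.0 - t_s23,
        180.0,
    ]
    return [(t, knoester_mean(t)) for t in angles]
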