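"""Exact evaluation of the FRET orientation factor for a single donor-acceptor pair.

The orientation factor kappa^2 couples the relative orientation of the donor
and acceptor transition dipoles, and of the vector joining their centers, to
the dipole-dipole energy-transfer rate:

    kappa^2 = (u_D . u_A - 3 (r . u_D)(r . u_A))^2

where ``u_D`` and ``u_A`` are unit vectors along the two transition dipoles
and ``r`` is the unit vector along the donor-acceptor separation.  Its value
lies in [0, 4]; the extremes correspond to mutually perpendicular dipole
arrangements (0) and collinear dipoles (4).

Conventions used throughout the package: the membrane normal is the +z axis,
membrane planes are planes of constant z, and dipole tilt angles theta are
measured from +z.  Dipoles are headless axes: kappa^2 is even in each dipole,
so the sign of a dipole vector never matters.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "unit_vector_from_tilt_azimuth",
    "kappa_squared",
    "kappa_squared_components",
]

#: numeric tolerance on the unit-modulus invariant of dipole vectors
UNIT_TOL = 1e-12


def unit_vector_from_tilt_azimuth(theta: float, phi: float) -> np.ndarray:
    """Cartesian unit vector from tilt ``theta`` (from +z) and azimuth ``phi``.

    Parameters
    ----------
    theta : float
        Tilt angle from the membrane normal, radians, in [0, pi].
    phi : float
        Azimuth in the membrane plane, radians, in [0, 2*pi).

    Returns
    -------
    numpy.ndarray, shape (3,)
        ``(sin(theta)cos(phi), sin(theta)sin(phi), cos(theta))``.
    """
    if not 0.0 <= theta <= math.pi:
        raise ValueError(f"tilt angle theta={theta!r} outside [0, pi]")
    if not 0.0 <= phi < 2.0 * math.pi:
        raise ValueError(f"azimuth phi={phi!r} outside [0, 2*pi)")
    st = math.sin(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), math.cos(theta)])


def kappa_squared(u_d, u_a, sep) -> float:
    """Orientation factor for one donor-acceptor pair.

    Parameters
    ----------
    u_d, u_a : array-like, shape (3,)
        Unit vectors along the donor and acceptor transition dipoles.
    sep : array-like, shape (3,)
        Separation vector from donor to acceptor (any length unit); must be
        nonzero.  Only its direction enters the result.

    Returns
    -------
    float
        kappa^2 in [0, 4].  Symmetric under donor/acceptor exchange and under
        sign flips of either dipole or of the separation.
    """
    u_d = np.asarray(u_d, dtype=float)
    u_a = np.asarray(u_a, dtype=float)
    sep = np.asarray(sep, dtype=float)
    for name, u in (("u_d", u_d), ("u_a", u_a)):
        norm2 = float(u @ u)
        if abs(norm2 - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a unit vector (|{name}|^2 = {norm2})")
    r2 = float(sep @ sep)
    if r2 == 0.0:
        raise ValueError("degenerate geometry: zero-length donor-acceptor separation")
    r_hat = sep / math.sqrt(r2)
    # 3*(rd*ra) keeps the expression bitwise symmetric under donor/acceptor
    # exchange (float products commute)
    val = float(u_d @ u_a) - 3.0 * (float(r_hat @ u_d) * float(r_hat @ u_a))
    return val * val


def kappa_squared_components(
    udx, udy, udz, uax, uay, uaz, rx, ry, rz
) -> np.ndarray:
    """Vectorized kappa^2 from Cartesian components of dipoles and separation.

    All arguments broadcast; the separation (rx, ry, rz) need not be
    normalized (it must be nonzero).  Used by the Monte-Carlo engines.
    """
    r2 = rx * rx + ry * ry + rz * rz
    inv_r = 1.0 / np.sqrt(r2)
    dot = udx * uax + udy * uay + udz * uaz
    rd = (rx * udx + ry * udy + rz * udz) * inv_r
    ra = (rx * uax + ry * uay + rz * uaz) * inv_r
    val = dot - 3.0 * (rd * ra)
    return val * val
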