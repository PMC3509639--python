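"""Sampling of membrane-probe transition-dipole orientations.

The tilt of a fluorophore's transition dipole relative to the membrane
normal is modelled through its cosine: cos(theta) is drawn from a Gaussian
centered on cos(theta_max) with standard deviation sigma, truncated to
[-1, 1] by rejection.  The azimuth phi is uniform on [0, 2*pi).  theta_max
is the most probable tilt; sigma measures the orientational heterogeneity
of the probe (sigma = 0 is a perfectly ordered dipole at fixed tilt, while
sigma >> 1 reproduces an isotropic orientation distribution with tilt
density sin(theta)/2).

Gaussian deviates are produced by the Box-Muller transform by default; the
ziggurat-style generator of ``numpy.random.Generator`` can be selected
instead (the two are distributionally identical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "AngularDistributionSpec",
    "DipoleOrientation",
    "sample_cos_theta",
    "sample_orientation",
    "theta_histogram",
]

# Rejection resampling redraws only out-of-range entries; each round at least
# halves the expected amount of remaining work for any admissible spec, so
# this cap is unreachable in practice and exists purely as a safety net.
MAX_REJECTION_ROUNDS = 10_000


@dataclass(frozen=True)
class AngularDistributionSpec:
    """Orientation distribution of one fluorophore species.

    Parameters
    ----------
    theta_max_deg : float
        Most probable tilt from the membrane normal, degrees, in [0, 180].
    sigma : float
        Standard deviation of the Gaussian in cos(theta) (dimensionless,
        >= 0).  ``sigma = 0`` is a delta distribution at ``theta_max_deg``.
    """

    theta_max_deg: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_max_deg <= 180.0:
            raise ValueError(
                f"theta_max_deg={self.theta_max_deg!r} outside [0, 180]"
            )
        if self.sigma < 0.0:
            raise ValueError(f"sigma={self.sigma!r} must be >= 0")

    @property
    def cos_theta_max(self) -> float:
        c = math.cos(math.radians(self.theta_max_deg))
        # snap the 90-degree case to exactly zero
        return 0.0 if abs(c) < 1e-15 else c


class DipoleOrientation(NamedTuple):
    """One sampled dipole orientation (radians)."""

    theta: float
    phi: float


def _normal_box_muller(rng: np.random.Generator, n: int) -> np.ndarray:
    """n standard-normal deviates via the Box-Muller transform."""
    m = (n + 1) // 2
    u1 = rng.random(m)
    u2 = rng.random(m)
    # u1 = 0 would give an infinite radius; map it to the top of the interval
    u1[u1 == 0.0] = 1.0
    r = np.sqrt(-2.0 * np.log(u1))
    w = 2.0 * math.pi * u2
    return np.concatenate((r * np.cos(w), r * np.sin(w)))[:n]


def _normal(rng: np.random.Generator, n: int, method: str) -> np.ndarray:
    if method == "box-muller":
        return _normal_box_muller(rng, n)
    if method == "ziggurat":
        return rng.standard_normal(n)
    raise ValueError(f"unknown normal generator {method!r}")


def sample_cos_theta(
    spec: AngularDistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
    method: str = "box-muller",
):
    """Draw cos(theta) from the truncated Gaussian of ``spec``.

    Out-of-range deviates (outside [-1, 1]) are rejected and redrawn, which
    realizes the truncated-normal distribution exactly.  For ``sigma = 0``
    the value is ``cos(theta_max)`` with no random draw.

    Returns a float if ``size`` is None, else an ndarray of shape (size,).
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    mu = spec.cos_theta_max
    if spec.sigma == 0.0:
        out = np.full(n, mu)
    else:
        out = mu + spec.sigma * _normal(rng, n, method)
        bad = np.flatnonzero(np.abs(out) > 1.0)
        rounds = 0
        while bad.size:
            rounds += 1
            if rounds > MAX_REJECTION_ROUNDS:
                raise RuntimeError(
                    "truncated-Gaussian rejection sampling failed to "
                    f"converge for spec {spec!r}"
                )
            fresh = mu + spec.sigma * _normal(rng, bad.size, method)
            out[bad] = fresh
            bad = bad[np.abs(fresh) > 1.0]
    return float(out[0]) if scalar else out


def sample_orientation(
    spec: AngularDistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
    method: str = "box-muller",
):
    """Draw (theta, phi): theta = arccos of a truncated-Gaussian cosine,
    phi uniform on [0, 2*pi).

    Returns a :class:`DipoleOrientation` if ``size`` is None, else a pair of
    ndarrays ``(theta, phi)``.
    """
    c = sample_cos_theta(spec, rng, size=size, method=method)
    if size is None:
        return DipoleOrientation(math.acos(c), float(rng.uniform(0.0, 2.0 * math.pi)))
    return np.arccos(c), rng.uniform(0.0, 2.0 * math.pi, int(size))


def theta_histogram(thetas, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized tilt-angle density over [0, pi].

    Parameters
    ----------
    thetas : array-like of float, or iterable of DipoleOrientation
        Tilt angles in radians (orientations are reduced to their theta).
    n_bins : int
        Number of equal-width bins over [0, pi].

    Returns
    -------
    (bin_edges, density)
        ``density`` integrates to 1 over [0, pi].
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    arr = np.asarray(
        [o.theta if isinstance(o, DipoleOrientation) else o for o in np.atleast_1d(thetas)]
        if not isinstance(thetas, np.ndarray)
        else thetas,
        dtype=float,
    )
    if arr.size == 0:
        raise ValueError("cannot histogram an empty sample set")
    density, edges = np.histogram(arr, bins=n_bins, range=(0.0, math.pi), density=True)
    return edges, density
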