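"""Shared fixtures and oracles for the kappa2sim test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import truncnorm


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniformly distributed unit vectors, shape (n, 3)."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def cos2_moment(theta_max_deg: float, sigma: float) -> float:
    """<cos^2 theta> of the truncated-Gaussian tilt distribution.

    Independent oracle via scipy's truncated normal; sigma = 0 collapses to
    the delta distribution at theta_max.
    """
    mu = math.cos(math.radians(theta_max_deg))
    if sigma == 0.0:
        return mu * mu
    d = truncnorm((-1.0 - mu) / sigma, (1.0 - mu) / sigma, loc=mu, scale=sigma)
    return float(d.var() + d.mean() ** 2)


def coplanar_mean_oracle(
    theta_d: float, sigma_d: float, theta_a: float, sigma_a: float
) -> float:
    """Exact <kappa^2> for coplanar, azimuthally uniform, independent dipoles.

    With second moments m = <cos^2 theta> per species and the in-plane
    separation direction, the second-moment matrix of each dipole is
    diag(a, a, m) with a = (1 - m)/2, and expanding kappa^2 gives

        <kappa^2> = 5 a_D a_A + m_D m_A.

    Reduces to the Knoester-van Himbergen expression for sigma = 0 and
    identical tilts, and to 2/3 for isotropic moments (m = 1/3).
    """
    m_d = cos2_moment(theta_d, sigma_d)
    m_a = cos2_moment(theta_a, sigma_a)
    return 5.0 * (1.0 - m_d) / 2.0 * (1.0 - m_a) / 2.0 + m_d * m_a
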