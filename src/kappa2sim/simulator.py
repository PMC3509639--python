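"""Monte-Carlo engines for kappa^2 distributions of membrane-bound FRET pairs.

Two sampling schemes are provided.

``simulate_unweighted``
    Donors on the plane z = 0, acceptors on the plane z = h, both laterally
    uniform on an l x l square.  Each of the N pairs contributes one kappa^2
    value; the result is the plain histogram and arithmetic mean.  The
    ``simulate_unweighted_slab`` variant instead draws each acceptor's z
    uniformly in [0, slab_zmax], which reproduces a three-dimensional
    distribution of acceptors.

``simulate_weighted``
    Bilayer geometry: one donor plane and one or two acceptor planes at
    interplanar distances h1 (cis leaflet) and h2 (trans leaflet).  Pairs
    closer than the exclusion distance Re of their plane have their
    positions redrawn (steric contact limit).  Because the FRET rate to each
    acceptor scales as kappa_i^2 / R_i^6, the physically meaningful average
    pools both planes with inverse-sixth-power distance weights:

        <kappa^2> = sum_i kappa_i^2 / R_i^6  /  sum_i 1 / R_i^6

No periodic boundary conditions are applied: the finite box size l is part
of the model, and for non-coplanar planes the mean depends on l until l is
much larger than h.

All randomness flows from one seeded ``numpy.random.Generator`` per run,
with a fixed draw order (donor positions, acceptor positions, donor
orientations, acceptor orientations, per chunk), so results are bit-for-bit
reproducible at a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .orientation import AngularDistributionSpec, sample_cos_theta

__all__ = [
    "GeometryConfig",
    "Kappa2Result",
    "RepeatSummary",
    "simulate_unweighted",
    "simulate_unweighted_slab",
    "simulate_weighted",
    "repeat_runs",
]

KAPPA2_MAX = 4.0

# pairs processed per vectorized block; bounds peak memory at ~15 arrays of
# this length without affecting results
_CHUNK = 1_000_000

# rounds of position redraws for exclusion-zone violations before declaring
# the geometry infeasible
_MAX_REPLACE_ROUNDS = 10_000


@dataclass(frozen=True)
class GeometryConfig:
    """Spatial configuration of a simulation run.

    Parameters
    ----------
    l : float
        Side of the square simulation box, nm.
    n_pairs : int
        Number of donor-acceptor pairs per plane.
    h : float
        Donor-acceptor interplanar distance for the unweighted engine, nm.
    h1, h2 : float or None
        Interplanar distances of the two acceptor planes for the weighted
        engine, nm.  ``h2 = None`` runs a single acceptor plane.
    re1, re2 : float
        Exclusion distances (minimum 3D donor-acceptor separation) for the
        two planes, nm.  A coplanar plane (h = 0) requires Re > 0 when
        distance weighting is used, otherwise the 1/R^6 weight diverges.
    slab_zmax : float or None
        If set, the unweighted slab engine draws acceptor z uniformly in
        [0, slab_zmax] instead of fixing it at h.
    n_bins : int
        Equal-width kappa^2 histogram bins over [0, 4].
    seed : int
        Seed of the run's random stream.
    normal_method : str
        ``"box-muller"`` (default) or ``"ziggurat"`` Gaussian generator.
    """

    l: float = 100.0
    n_pairs: int = 1_000_000
    h: float = 0.0
    h1: float | None = None
    h2: float | None = None
    re1: float = 0.0
    re2: float = 0.0
    slab_zmax: float | None = None
    n_bins: int = 100
    seed: int = 0
    normal_method: str = "box-muller"

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("box side l must be > 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        for name in ("h", "re1", "re2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("h1", "h2", "slab_zmax"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Kappa2Result:
    """Histogrammed kappa^2 distribution and its averages.

    ``density`` integrates to 1 over the bin edges; for weighted runs it is
    the pooled unweighted histogram over both planes, with the per-plane
    histograms in ``plane_densities``.  ``mean_weighted`` is present only
    for weighted runs.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    mean_unweighted: float
    mean_weighted: float | None
    theta_d_hist: tuple[np.ndarray, np.ndarray]
    theta_a_hist: tuple[np.ndarray, np.ndarray]
    n_pairs: int
    seed: int
    max_kappa2: float
    plane_densities: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        """The physically relevant average: weighted if available."""
        return self.mean_weighted if self.mean_weighted is not None else self.mean_unweighted


@dataclass
class RepeatSummary:
    """Per-run means of repeated simulations and their spread."""

    means: list[float]
    grand_mean: float
    std_dev: float
    n_repeats: int


class _Accumulator:
    """Streaming histogram + moment accumulation over chunks."""

    def __init__(self, n_bins: int) -> None:
        self.k2_edges = np.linspace(0.0, KAPPA2_MAX, n_bins + 1)
        self.th_edges = np.linspace(0.0, math.pi, n_bins + 1)
        self.k2_counts = np.zeros(n_bins)
        self.th_d_counts = np.zeros(n_bins)
        self.th_a_counts = np.zeros(n_bins)
        self.sum_k2 = 0.0
        self.sum_wk2 = 0.0
        self.sum_w = 0.0
        self.n = 0
        self.max_k2 = 0.0

    def add(self, k2, cos_d, cos_a, r2=None) -> None:
        self.k2_counts += np.histogram(k2, bins=self.k2_edges)[0]
        self.th_d_counts += np.histogram(np.arccos(cos_d), bins=self.th_edges)[0]
        self.th_a_counts += np.histogram(np.arccos(cos_a), bins=self.th_edges)[0]
        self.sum_k2 += float(k2.sum())
        self.n += k2.size
        self.max_k2 = max(self.max_k2, float(k2.max()))
        if r2 is not None:
            w = r2 ** -3  # 1/R^6
            self.sum_w += float(w.sum())
            self.sum_wk2 += float((w * k2).sum())

    def density(self) -> np.ndarray:
        width = self.k2_edges[1] - self.k2_edges[0]
        return self.k2_counts / (self.n * width)

    def theta_density(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        width = self.th_edges[1] - self.th_edges[0]
        return self.th_edges, counts / (self.n * width)


def _draw_positions(rng: np.random.Generator, m: int, l: float):
    xd = rng.uniform(0.0, l, m)
    yd = rng.uniform(0.0, l, m)
    xa = rng.uniform(0.0, l, m)
    ya = rng.uniform(0.0, l, m)
    return xd, yd, xa, ya


def _chunk_kappa2(
    rng: np.random.Generator,
    m: int,
    donor_spec: AngularDistributionSpec,
    acceptor_spec: AngularDistributionSpec,
    geom: GeometryConfig,
    dz: float | None,
    re: float,
    slab_zmax: float | None,
):
    """kappa^2, cos(theta_D), cos(theta_A), R^2 for one chunk of m pairs.

    ``dz`` is the fixed interplanar distance, or None to draw acceptor z
    uniformly in [0, slab_zmax].  Pairs with 3D separation below ``re`` (or
    exactly zero) have their positions redrawn, orientations kept.
    """
    l = geom.l
    xd, yd, xa, ya = _draw_positions(rng, m, l)
    if slab_zmax is None:
        rz = np.full(m, float(dz))
    else:
        rz = rng.uniform(0.0, slab_zmax, m)
    rx = xa - xd
    ry = ya - yd
    r2 = rx * rx + ry * ry + rz * rz
    re2 = re * re
    bad = np.flatnonzero(r2 <= re2) if re > 0 else np.flatnonzero(r2 == 0.0)
    rounds = 0
    while bad.size:
        rounds += 1
        if rounds > _MAX_REPLACE_ROUNDS:
            raise RuntimeError(
                f"exclusion distance Re={re} infeasible for box l={l}, "
                f"interplanar offset {dz}"
            )
        nb = bad.size
        bxd, byd, bxa, bya = _draw_positions(rng, nb, l)
        if slab_zmax is not None:
            rz[bad] = rng.uniform(0.0, slab_zmax, nb)
        brx = bxa - bxd
        bry = bya - byd
        br2 = brx * brx + bry * bry + rz[bad] ** 2
        rx[bad] = brx
        ry[bad] = bry
        r2[bad] = br2
        bad = bad[br2 <= re2] if re > 0 else bad[br2 == 0.0]

    method = geom.normal_method
    cos_d = sample_cos_theta(donor_spec, rng, size=m, method=method)
    phi_d = rng.uniform(0.0, 2.0 * math.pi, m)
    cos_a = sample_cos_theta(acceptor_spec, rng, size=m, method=method)
    phi_a = rng.uniform(0.0, 2.0 * math.pi, m)

    sin_d = np.sqrt(1.0 - cos_d * cos_d)
    sin_a = np.sqrt(1.0 - cos_a * cos_a)
    udx = sin_d * np.cos(phi_d)
    udy = sin_d * np.sin(phi_d)
    uax = sin_a * np.cos(phi_a)
    uay = sin_a * np.sin(phi_a)

    inv_r = 1.0 / np.sqrt(r2)
    dot = udx * uax + udy * uay + cos_d * cos_a
    rd = (rx * udx + ry * udy + rz * cos_d) * inv_r
    ra = (rx * uax + ry * uay + rz * cos_a) * inv_r
    val = dot - 3.0 * rd * ra
    return val * val, cos_d, cos_a, r2


def _run_plane(
    acc: _Accumulator,
    rng: np.random.Generator,
    donor_spec: AngularDistributionSpec,
    acceptor_spec: AngularDistributionSpec,
    geom: GeometryConfig,
    dz: float | None,
    re: float,
    slab_zmax: float | None,
    weighted: bool,
) -> np.ndarray:
    """Accumulate one full cycle of geom.n_pairs pairs; return plane counts."""
    start_counts = acc.k2_counts.copy()
    remaining = geom.n_pairs
    while remaining:
        m = min(remaining, _CHUNK)
        k2, cos_d, cos_a, r2 = _chunk_kappa2(
            rng, m, donor_spec, acceptor_spec, geom, dz, re, slab_zmax
        )
        acc.add(k2, cos_d, cos_a, r2 if weighted else None)
        remaining -= m
    return acc.k2_counts - start_counts


def _finalize(acc: _Accumulator, geom: GeometryConfig, weighted: bool,
              plane_counts: Sequence[np.ndarray] = ()) -> Kappa2Result:
    width = acc.k2_edges[1] - acc.k2_edges[0]
    return Kappa2Result(
        bin_edges=acc.k2_edges,
        density=acc.density(),
        mean_unweighted=acc.sum_k2 / acc.n,
        mean_weighted=(acc.sum_wk2 / acc.sum_w) if weighted else None,
        theta_d_hist=acc.theta_density(acc.th_d_counts),
        theta_a_hist=acc.theta_density(acc.th_a_counts),
        n_pairs=acc.n,
        seed=geom.seed,
        max_kappa2=acc.max_k2,
        plane_densities=[
            c / (geom.n_pairs * width) for c in plane_counts
        ],
    )


def simulate_unweighted(
    donor_spec: AngularDistributionSpec,
    acceptor_spec: AngularDistributionSpec,
    geom: GeometryConfig,
) -> Kappa2Result:
    """Plain kappa^2 distribution and mean for one acceptor plane at z = h."""
    if geom.slab_zmax is not None:
        raise ValueError("slab_zmax set: use simulate_unweighted_slab")
    rng = np.random.default_rng(geom.seed)
    acc = _Accumulator(geom.n_bins)
    _run_plane(acc, rng, donor_spec, acceptor_spec, geom,
               dz=geom.h, re=0.0, slab_zmax=None, weighted=False)
    return _finalize(acc, geom, weighted=False)


def simulate_unweighted_slab(
    donor_spec: AngularDistributionSpec,
    acceptor_spec: AngularDistributionSpec,
    geom: GeometryConfig,
) -> Kappa2Result:
    """As :func:`simulate_unweighted`, but acceptor z ~ U[0, slab_zmax].

    Emulates acceptors distributed through a three-dimensional slab rather
    than on a single plane.
    """
    if geom.slab_zmax is None or geom.slab_zmax <= 0:
        raise ValueError("simulate_unweighted_slab requires slab_zmax > 0")
    rng = np.random.default_rng(geom.seed)
    acc = _Accumulator(geom.n_bins)
    _run_plane(acc, rng, donor_spec, acceptor_spec, geom,
               dz=None, re=0.0, slab_zmax=geom.slab_zmax, weighted=False)
    return _finalize(acc, geom, weighted=False)


def simulate_weighted(
    donor_spec: AngularDistributionSpec,
    acceptor_spec: AngularDistributionSpec,
    geom: GeometryConfig,
) -> Kappa2Result:
    """R^-6-weighted <kappa^2> over one or two acceptor planes.

    Runs one cycle of ``n_pairs`` pairs per configured plane (h1, and h2 if
    present), with per-plane exclusion distances re1/re2 enforced on the 3D
    separation.  Partial sums of kappa^2/R^6 and 1/R^6 are pooled across
    planes, so equal pair counts imply equal acceptor surface densities in
    the two leaflets.
    """
    if geom.h1 is None:
        raise ValueError("simulate_weighted requires h1 (first acceptor plane)")
    planes = [(geom.h1, geom.re1)]
    if geom.h2 is not None:
        planes.append((geom.h2, geom.re2))
    for dz, re in planes:
        if dz == 0.0 and re <= 0.0:
            raise ValueError(
                "a coplanar acceptor plane (h = 0) requires an exclusion "
                "distance Re > 0 under 1/R^6 weighting"
            )
    rng = np.random.default_rng(geom.seed)
    acc = _Accumulator(geom.n_bins)
    plane_counts = [
        _run_plane(acc, rng, donor_spec, acceptor_spec, geom,
                   dz=dz, re=re, slab_zmax=None, weighted=True)
        for dz, re in planes
    ]
    return _finalize(acc, geom, weighted=True, plane_counts=plane_counts)


def repeat_runs(
    sim: Callable[[AngularDistributionSpec, AngularDistributionSpec, GeometryConfig], Kappa2Result],
    donor_spec: AngularDistributionSpec,
    acceptor_spec: AngularDistributionSpec,
    geom: GeometryConfig,
    n_repeats: int = 10,
    base_seed: int = 1,
    seeds: Sequence[int] | None = None,
) -> RepeatSummary:
    """Run ``sim`` repeatedly with distinct seeds to assess convergence.

    Seeds are ``base_seed .. base_seed + n_repeats - 1`` unless an explicit
    ``seeds`` sequence is given.  The summary reports each run's mean (the
    weighted mean when the engine produces one), their grand mean, and the
    sample standard deviation across runs.
    """
    if seeds is None:
        if n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        seeds = [base_seed + k for k in range(n_repeats)]
    seeds = list(seeds)
    means = [
        sim(donor_spec, acceptor_spec, dataclasses.replace(geom, seed=s)).mean
        for s in seeds
    ]
    arr = np.asarray(means)
    return RepeatSummary(
        means=means,
        grand_mean=float(arr.mean()),
        std_dev=float(arr.std(ddof=1)),
        n_repeats=len(seeds),
    )
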