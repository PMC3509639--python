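"""Tests of the Monte-Carlo kappa^2 engines."""

import dataclasses
import math

import numpy as np
import pytest

from kappa2sim.core_geometry import kappa_squared, unit_vector_from_tilt_azimuth
from kappa2sim.orientation import AngularDistributionSpec, sample_cos_theta
from kappa2sim.simulator import (
    GeometryConfig,
    repeat_runs,
    simulate_unweighted,
    simulate_unweighted_slab,
    simulate_weighted,
)

from conftest import coplanar_mean_oracle

ISO = AngularDistributionSpec(90.0, 50.0)
S90 = AngularDistributionSpec(90.0, 0.0)
VERTICAL = AngularDistributionSpec(0.0, 0.0)


def mc_se(result):
    """Monte-Carlo standard error of the unweighted mean, from the histogram."""
    mid = 0.5 * (result.bin_edges[:-1] + result.bin_edges[1:])
    w = result.density * np.diff(result.bin_edges)
    var = float((w * (mid - result.mean_unweighted) ** 2).sum())
    return math.sqrt(var / result.n_pairs)


def test_geometry_validation():
    with pytest.raises(ValueError):
        GeometryConfig(l=0.0)
    with pytest.raises(ValueError):
        GeometryConfig(n_pairs=0)
    with pytest.raises(ValueError):
        GeometryConfig(h=-1.0)
    with pytest.raises(ValueError):
        GeometryConfig(n_bins=0)


def test_result_invariants():
    res = simulate_unweighted(
        AngularDistributionSpec(70.0, 0.3),
        AngularDistributionSpec(110.0, 0.2),
        GeometryConfig(n_pairs=50_000, seed=3, h=1.0),
    )
    width = np.diff(res.bin_edges)
    assert float((res.density * width).sum()) == pytest.approx(1.0, abs=1e-9)
    assert np.all(res.density >= 0)
    assert 0.0 <= res.mean_unweighted <= 4.0
    assert res.max_kappa2 <= 4.0 + 1e-12
    for edges, dens in (res.theta_d_hist, res.theta_a_hist):
        assert float((dens * np.diff(edges)).sum()) == pytest.approx(1.0, abs=1e-9)
    assert res.n_pairs == 50_000


def test_vertical_coplanar_pairs_are_invariant():
    """Dipoles along the membrane normal with in-plane separation always give
    kappa^2 = 1 exactly: the distribution is a delta."""
    res = simulate_unweighted(VERTICAL, VERTICAL, GeometryConfig(n_pairs=10_000, seed=1))
    assert res.mean_unweighted == 1.0
    assert res.max_kappa2 == 1.0
    width = res.bin_edges[1] - res.bin_edges[0]
    bin_of_one = np.flatnonzero(res.density)
    assert bin_of_one.size == 1
    assert res.density[bin_of_one[0]] == pytest.approx(1.0 / width)


def test_engine_matches_scalar_loop_reference():
    """The vectorized engine reproduces, to 1e-12, a plain scalar loop over
    the same sampled positions and orientations using the documented draw
    order (donor xy, acceptor xy, donor orientation, acceptor orientation)."""
    geom = GeometryConfig(l=10.0, n_pairs=1000, h=1.3, seed=99)
    donor = AngularDistributionSpec(35.0, 0.25)
    acceptor = AngularDistributionSpec(140.0, 0.4)
    res = simulate_unweighted(donor, acceptor, geom)

    rng = np.random.default_rng(geom.seed)
    m = geom.n_pairs
    xd = rng.uniform(0, geom.l, m)
    yd = rng.uniform(0, geom.l, m)
    xa = rng.uniform(0, geom.l, m)
    ya = rng.uniform(0, geom.l, m)
    cd = sample_cos_theta(donor, rng, size=m)
    pd_ = rng.uniform(0, 2 * math.pi, m)
    ca = sample_cos_theta(acceptor, rng, size=m)
    pa = rng.uniform(0, 2 * math.pi, m)
    k2 = np.array([
        kappa_squared(
            unit_vector_from_tilt_azimuth(math.acos(cd[i]), pd_[i]),
            unit_vector_from_tilt_azimuth(math.acos(ca[i]), pa[i]),
            (xa[i] - xd[i], ya[i] - yd[i], geom.h),
        )
        for i in range(m)
    ])
    assert res.mean_unweighted == pytest.approx(k2.mean(), abs=1e-12)
    counts = np.histogram(k2, bins=res.bin_edges)[0]
    np.testing.assert_array_equal(
        counts, np.rint(res.density * np.diff(res.bin_edges) * m).astype(int)
    )


def test_same_seed_reproduces_bitwise():
    geom = GeometryConfig(n_pairs=20_000, seed=5, h=0.5)
    a = simulate_unweighted(S90, ISO, geom)
    b = simulate_unweighted(S90, ISO, geom)
    assert a.mean_unweighted == b.mean_unweighted
    np.testing.assert_array_equal(a.density, b.density)


@pytest.mark.parametrize(
    "donor, acceptor",
    [
        (S90, S90),
        (AngularDistributionSpec(60.0, 0.0), AngularDistributionSpec(120.0, 0.0)),
        (AngularDistributionSpec(20.0, 0.15), AngularDistributionSpec(0.0, 0.35)),
        (AngularDistributionSpec(90.0, 3.0), AngularDistributionSpec(90.0, 3.0)),
        (AngularDistributionSpec(125.0, 0.35), AngularDistributionSpec(77.0, 0.25)),
    ],
)
def test_coplanar_mean_matches_moment_oracle(donor, acceptor):
    """Coplanar unweighted means agree with the exact second-moment identity
    <kappa^2> = 5 a_D a_A + m_D m_A (4 standard errors at N = 2e5)."""
    res = simulate_unweighted(donor, acceptor, GeometryConfig(n_pairs=200_000, seed=11))
    oracle = coplanar_mean_oracle(
        donor.theta_max_deg, donor.sigma, acceptor.theta_max_deg, acceptor.sigma
    )
    assert res.mean_unweighted == pytest.approx(oracle, abs=4 * mc_se(res))


def test_coplanar_results_independent_of_box_size():
    """For h = 0 the kappa^2 distribution does not depend on l."""
    means = []
    ses = []
    for i, l in enumerate((1.0, 2.0, 4.0, 8.0, 100.0)):
        res = simulate_unweighted(S90, S90, GeometryConfig(l=l, n_pairs=100_000, seed=40 + i))
        means.append(res.mean_unweighted)
        ses.append(mc_se(res))
    for m, s in zip(means, ses):
        assert m == pytest.approx(1.25, abs=3 * s)


def test_parallel_plane_mean_depends_on_box_size():
    """For h = 2 nm the mean shifts at small l and approaches the coplanar
    value as l grows."""
    devs = []
    for i, l in enumerate((2.0, 8.0, 100.0)):
        res = simulate_unweighted(
            S90, S90, GeometryConfig(l=l, n_pairs=200_000, h=2.0, seed=50 + i)
        )
        devs.append(abs(res.mean_unweighted - 1.25))
    assert devs[0] > devs[1] > devs[2]
    assert devs[0] > 0.05          # strong finite-size effect at l = h
    assert devs[2] < 0.02          # nearly coplanar at l = 100 nm


def test_donor_acceptor_exchange_symmetry():
    d = AngularDistributionSpec(20.0, 0.15)
    a = AngularDistributionSpec(0.0, 0.35)
    r1 = simulate_unweighted(d, a, GeometryConfig(n_pairs=200_000, seed=60))
    r2 = simulate_unweighted(a, d, GeometryConfig(n_pairs=200_000, seed=61))
    se = math.hypot(mc_se(r1), mc_se(r2))
    assert r1.mean_unweighted == pytest.approx(r2.mean_unweighted, abs=3 * se)


def test_tilt_mirror_symmetry():
    d = AngularDistributionSpec(60.0, 0.1)
    a = AngularDistributionSpec(120.0, 0.2)
    dm = AngularDistributionSpec(120.0, 0.1)
    am = AngularDistributionSpec(60.0, 0.2)
    r1 = simulate_unweighted(d, a, GeometryConfig(n_pairs=200_000, seed=62, h=1.0))
    r2 = simulate_unweighted(dm, am, GeometryConfig(n_pairs=200_000, seed=63, h=1.0))
    se = math.hypot(mc_se(r1), mc_se(r2))
    assert r1.mean_unweighted == pytest.approx(r2.mean_unweighted, abs=3 * se)


def test_slab_isotropic_recovers_two_thirds():
    """Acceptors spread through a 5 nm slab with isotropic orientations give
    the 3D isotropic average 2/3 (within 0.005 at N = 1e6)."""
    res = simulate_unweighted_slab(
        ISO, ISO, GeometryConfig(n_pairs=1_000_000, slab_zmax=5.0, seed=70)
    )
    assert res.mean_unweighted == pytest.approx(2.0 / 3.0, abs=0.005)


def test_slab_vertical_dipoles_exceed_one():
    """With out-of-plane separations, z-aligned dipoles average above 1;
    oracle 1.0105 from a direct 1e6-pair brute-force evaluation."""
    res = simulate_unweighted_slab(
        VERTICAL, VERTICAL,
        GeometryConfig(l=2.0, n_pairs=1_000_000, slab_zmax=2.0, seed=71),
    )
    assert res.mean_unweighted > 1.0
    assert res.mean_unweighted == pytest.approx(1.0105, abs=0.005)


def test_slab_requires_zmax_and_unweighted_rejects_it():
    with pytest.raises(ValueError):
        simulate_unweighted_slab(ISO, ISO, GeometryConfig(n_pairs=100))
    with pytest.raises(ValueError):
        simulate_unweighted(ISO, ISO, GeometryConfig(n_pairs=100, slab_zmax=1.0))


def test_weighted_requires_h1_and_guards_coplanar_divergence():
    with pytest.raises(ValueError):
        simulate_weighted(S90, S90, GeometryConfig(n_pairs=100))
    with pytest.raises(ValueError):
        simulate_weighted(S90, S90, GeometryConfig(n_pairs=100, h1=0.0, re1=0.0))


def test_weighted_exclusion_enforced():
    geom = GeometryConfig(l=5.0, n_pairs=50_000, h1=0.0, re1=0.8, seed=80)
    res = simulate_weighted(S90, S90, geom)
    assert res.mean_weighted is not None
    assert 0.0 <= res.mean_weighted <= 4.0
    # coplanar theta=0 dipoles give exactly kappa^2=1 regardless of weights
    res_v = simulate_weighted(VERTICAL, VERTICAL, geom)
    assert res_v.mean_weighted == pytest.approx(1.0, abs=1e-12)


def test_weighted_infeasible_exclusion_raises():
    with pytest.raises(RuntimeError, match="infeasible"):
        simulate_weighted(
            S90, S90, GeometryConfig(l=1.0, n_pairs=1000, h1=0.0, re1=5.0, seed=81)
        )


def test_weighted_equals_unweighted_when_distances_degenerate():
    """With l << h all pair distances coincide, so the 1/R^6 weights are
    constant and the weighted mean collapses onto the unweighted one."""
    geom = GeometryConfig(l=1e-4, n_pairs=100_000, h1=2.0, seed=82)
    res = simulate_weighted(S90, ISO, geom)
    assert res.mean_weighted == pytest.approx(res.mean_unweighted, abs=1e-6)


def test_weighted_two_planes_pools_partial_sums():
    """A two-plane run visits 2N pairs and its per-plane histograms each
    normalize over N pairs."""
    geom = GeometryConfig(l=20.0, n_pairs=30_000, h1=0.0, h2=2.0, re1=0.8, re2=0.8, seed=83)
    res = simulate_weighted(S90, S90, geom)
    assert res.n_pairs == 60_000
    assert len(res.plane_densities) == 2
    width = np.diff(res.bin_edges)
    for dens in res.plane_densities:
        assert float((dens * width).sum()) == pytest.approx(1.0, abs=1e-9)
    # pooled histogram is the average of the per-plane ones
    np.testing.assert_allclose(
        res.density, 0.5 * (res.plane_densities[0] + res.plane_densities[1]), atol=1e-12
    )


def test_repeat_runs_statistics():
    geom = GeometryConfig(n_pairs=20_000, seed=0)
    summary = repeat_runs(simulate_unweighted, ISO, ISO, geom, n_repeats=4, base_seed=100)
    assert summary.n_repeats == 4 and len(summary.means) == 4
    assert summary.std_dev >= 0.0
    assert summary.grand_mean == pytest.approx(np.mean(summary.means))
    # forced identical seeds: zero spread
    same = repeat_runs(simulate_unweighted, ISO, ISO, geom, seeds=[5, 5])
    assert same.std_dev == 0.0
    with pytest.raises(ValueError):
        repeat_runs(simulate_unweighted, ISO, ISO, geom, n_repeats=1)


def test_repeat_runs_grand_mean_consistent_with_isotropic_limit():
    """10 coplanar isotropic repeats at N = 1e5: the grand mean sits within
    3 standard errors of 2/3."""
    geom = GeometryConfig(n_pairs=100_000)
    summary = repeat_runs(simulate_unweighted, ISO, ISO, geom, n_repeats=10, base_seed=200)
    sem = summary.std_dev / math.sqrt(summary.n_repeats)
    assert summary.grand_mean == pytest.approx(2.0 / 3.0, abs=3 * sem)
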