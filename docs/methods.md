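# Methods

## Model

A donor-acceptor pair contributes the orientation factor

    kappa^2 = (u_D . u_A - 3 (r . u_D)(r . u_A))^2,

equivalently `(cos psi_T - 3 cos psi_D cos psi_A)^2` in terms of the angle
`psi_T` between the dipoles and the angles `psi_D`, `psi_A` each dipole
makes with the separation vector.  The value lies in [0, 4] and is even in
each dipole (dipoles are headless axes) and in the separation.

Fluorophores sit on planes normal to the z axis (the membrane normal).
Donor and acceptor lateral positions are independently uniform on an
`l x l` square; no periodic boundary conditions are applied, because the
finite box is part of the model — for acceptors in a plane at distance
`h > 0` the mean of kappa^2 genuinely depends on `l` until `l >> h`, while
for coplanar pairs the distribution is exactly independent of `l` (the
orientation statistics decouple from the pair distance).

Dipole tilts are generated through their cosines: `cos(theta)` is drawn
from a Gaussian centered at `cos(theta_max)` with standard deviation
`sigma`, truncated to [-1, 1] by rejection (out-of-range deviates are
redrawn, which realizes the truncated normal exactly); the azimuth is
uniform.  This truncated-Gaussian family covers the physically relevant
range: `sigma = 0` is a perfectly ordered probe at fixed tilt, moderate
`sigma` (0.05-0.5) matches the orientational heterogeneity of real
membrane probes, and `sigma >> 1` approaches the isotropic tilt density
`sin(theta)/2`.  The approach is asymptotic, not exact: at `sigma = 3` the
cos(theta) density still varies by `exp(1/18) - 1 ≈ 5.7%` across [-1, 1].
Tests that compare `sigma = 3` output against exact isotropic references
therefore use a 7% agreement band rather than a sharp goodness-of-fit
test, and a chi-square test is applied at `sigma = 50`, where the residual
anisotropy (~0.06%) is far below the Monte-Carlo resolution.

The model describes the dynamic regime only: orientations decorrelate
much faster than the donor lifetime, so each pair samples its orientation
distribution independently of its distance.  Static or intermediate
reorientation regimes, wobbling-in-cone dynamics, lateral inhomogeneity
(domains, pair correlations) and near-field corrections to the ideal
dipole-dipole coupling are all outside the model.

## Exact references used for validation

* Isotropic density: `p(k2) = ln(2+sqrt(3)) / (2 sqrt(3) sqrt(k2))` for
  `0 < k2 <= 1` and `p(k2) = ln((2+sqrt(3)) / (sqrt(k2)+sqrt(k2-1))) /
  (2 sqrt(3) sqrt(k2))` for `1 <= k2 <= 4`; unit normalization and mean
  2/3 are asserted by quadrature.
* Knoester-van Himbergen: for coplanar, identically tilted dipoles with
  `S = P2(cos theta)`, `<kappa^2> = 2/3 - (2/3)S + S^2`, with extrema 1.25
  (90 deg), 5/9 (41.81 deg and mirror) and 1 (0 and 180 deg), and four
  crossings of 2/3.
* Moment identity (used as a test oracle): for coplanar, azimuthally
  uniform, *independent* dipole distributions with second moments
  `m = <cos^2 theta>` per species, expanding kappa^2 gives
  `<kappa^2> = 5 a_D a_A + m_D m_A` with `a = (1-m)/2`.  This covers
  hetero pairs and any `sigma`, and shows that the `sigma = 3`
  configuration has exact mean 0.6716, not 2/3 — the residual of the
  truncation noted above.
* Support cutoff: at fixed tilt `theta` the coplanar kappa^2 support ends
  at `max((2 - cos^2 theta)^2, (3 cos^2 theta - 2)^2)`; at the magic angle
  `acos(1/sqrt(3)) = 54.7356 deg` this is exactly 25/9.  At the rounded
  tilt 54.74 deg the bound is 2.77810, which still equals 2.778 at three
  printed decimals.

## Distance weighting and estimator statistics

For one donor among many acceptors the transfer rate is
`k_T = C sum_i kappa_i^2 / R_i^6` with `C` pair-independent, so the
natural acceptor-averaged orientation factor weights each pair by
`1/R_i^6`.  The weighted engine runs one cycle of `N` pairs per acceptor
plane (equal pair counts mean equal acceptor surface densities in the two
leaflets), enforces the per-plane exclusion distance `Re` on the 3D
separation by redrawing positions only (orientations are kept; because
positions and orientations are independent, redrawing both would be
statistically equivalent), and pools the partial sums
`sum kappa^2/R^6` and `sum 1/R^6` across planes.

This ratio estimator is heavy-tailed by construction: with `l = 100 nm`
and `Re = 0.8 nm` the weights span ~13 orders of magnitude and the sums
are dominated by the few near-contact pairs, giving an effective sample
size of only ~250 per 10^6 pairs for a coplanar plane.  Run-to-run
standard deviations of 0.02-0.10 (depending on the orientation specs) are
therefore intrinsic at the default scale, and the package reports
repeated-run grand means: ten seeded repeats bring the grand-mean
standard error to roughly 0.01-0.03.  Tests compare grand means at three
combined standard errors (this package's SEM pooled with the reference
spread) rather than at face-value printed uncertainties, which are not
attainable with this estimator at this problem size.

## Decay law and efficiency

In reduced variables `zeta = t/tau0`, `alpha = R0bar/Re`,
`beta = (3/2)<kappa^2>` and `sigma_c = pi R0bar^2 c`, the donor survival
against a uniform plane of acceptors at minimum distance Re is

    i_DA(zeta) = exp(-zeta) exp{ -beta^(1/3) sigma_c [ gamma(2/3, beta alpha^6 zeta) zeta^(1/3)
                  - (1 - exp(-beta alpha^6 zeta)) / (beta^(1/3) alpha^2) ] },

with `gamma` the lower unnormalized incomplete gamma function — the only
convention under which the `Re -> 0` limit reproduces the classical
planar decay `exp(-sigma_c beta^(1/3) Gamma(2/3) zeta^(1/3))`.
Efficiency is `E = 1 - integral_0^inf i_DA dzeta` (the unquenched decay
integrates to exactly 1), evaluated by adaptive quadrature with absolute
tolerance 1e-10 and verified against a fixed-grid Simpson oracle on the
cusp-removing substitution `u = zeta^(1/3)`.  `E(sigma_c)` curves at
fixed `(alpha, beta)` are universal.  The Förster radius helper uses
`R0 = 0.02108 (kappa^2 Phi0 n^-4 J)^(1/6)` nm with the overlap integral
`J` in nm^4 M^-1 cm^-1.

## Numerical choices

* Histograms: `n_bins` equal-width bins (default 100) over [0, 4] for
  kappa^2 and over [0, pi] for tilts; right-open bins with the last bin
  closed; densities normalized to unit integral.
* Defaults: `l = 100 nm`, `N = 10^6` pairs per plane, `Re = 0.8 nm` for
  weighted runs, 10 repeats for preset runs — chosen so that coplanar
  weighted runs sample near-contact orientations well while one run stays
  in the seconds range on one CPU.
* Random numbers: one `numpy` PCG64 stream per run with a fixed draw
  order (donor positions, acceptor positions, donor orientations,
  acceptor orientations, per chunk of 10^6 pairs), so any run is
  bit-for-bit reproducible from its seed.  Gaussian deviates use the
  Box-Muller transform by default; a ziggurat option is provided and is
  distributionally identical.
* Rejection loops (cos-theta truncation, exclusion-zone redraws) redraw
  only the offending entries and abort with a diagnostic after 10^4
  rounds — unreachable for feasible configurations, and a genuine
  infeasibility (e.g. `Re` larger than the attainable separations) is
  reported rather than silently truncated.
* `cos(90 deg)` is snapped to exactly 0 so that `sigma = 0` specs at 90
  degrees are exact; a zero-length separation (probability-zero under
  continuous sampling) is guarded by a position redraw.
* Coplanar acceptor planes require `Re > 0` under weighting, otherwise
  the `1/R^6` weight diverges; this is validated up front.

## Probe-pair presets

The preset catalogue records, per fluorophore, the transverse distance
from the bilayer center and the `(theta_max, sigma)` orientation spec
compiled from published linear-dichroism, quenching and MD studies of
that probe; each fluorophore's parameters are identical wherever it
appears.  The two acceptor planes follow from the transverse locations:
`h1 = |z_D - z_A|` (cis leaflet) and `h2 = z_D + z_A` (trans leaflet).
The gel-phase t-PnA/DPH preset changes only the donor orientation spec to
(5 deg, 0.03), keeping the fluid transverse locations and the DPH
acceptor parameters.  For homo-transfer presets both species share one
spec.  Preset runs use the standard parameters above; at that scale the
grand means carry ~0.01-0.03 statistical uncertainty, which should be
kept in mind when comparing against literature values of similar
precision.

## What the generator does and does not emulate

The synthetic ensembles emulate laterally uniform, orientationally
independent probe distributions on flat parallel planes in the dynamic
regime.  They do not emulate lateral domain structure or probe-probe
correlations, membrane curvature or undulations, depth fluctuations of
the fluorophores (each plane is sharp), time-correlated reorientation, or
donor-donor migration.  Agreement of the test suite therefore validates
the sampling and averaging machinery and the limiting-case physics; for
real membranes the input orientation distributions and transverse
locations remain the dominant source of uncertainty.
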