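# kappa2sim

Monte-Carlo estimation of the FRET orientation factor distribution for
membrane-embedded donor/acceptor fluorophores.

## The problem

Förster resonance energy transfer (FRET) rates depend on the mutual
orientation of the donor and acceptor transition dipoles through the
orientation factor

    kappa^2 = (u_D . u_A - 3 (r . u_D)(r . u_A))^2 ,   0 <= kappa^2 <= 4,

where `u_D`, `u_A` are unit vectors along the dipoles and `r` the unit
vector joining their centers.  The Förster radius scales as
`R0 ~ (kappa^2)^(1/6)`, so quantitative FRET analyses need an estimate of
`<kappa^2>`.  The ubiquitous dynamic-isotropic value 2/3 is often wrong in
membranes: lipid-bound probes have anisotropic, sometimes narrow,
orientation distributions with respect to the bilayer normal.

`kappa2sim` estimates the full probability density and average of kappa^2
in the fast-reorientation (dynamic) regime for probes confined to parallel
membrane planes.  Inputs are per-fluorophore orientation distributions —
most probable tilt `theta_max` from the membrane normal and a Gaussian
spread `sigma` in cos(theta), truncated to [-1, 1] — plus the planar
geometry (box size `l`, interplanar distances, exclusion distances).
Because the FRET rate to acceptor *i* scales as `kappa_i^2 / R_i^6`, the
physically meaningful average over a distribution of acceptors is the
inverse-sixth-power weighted mean

    <kappa^2> = sum_i kappa_i^2 / R_i^6  /  sum_i 1 / R_i^6 ,

which the bilayer engine pools over the cis and trans acceptor leaflets.
Closed-form anchors (the isotropic kappa^2 density with mean 2/3, and the
Knoester–van Himbergen average `2/3 - (2/3)S + S^2` with
`S = (3 cos^2(theta) - 1)/2` for identically oriented planar dipoles) are
included for validation, and the planar energy-transfer decay law with its
lower-incomplete-gamma term converts `<kappa^2>` into observable FRET
efficiencies.

## Worked example

Bilayer run with both dipoles fixed at 90 degrees from the membrane
normal, acceptor planes at 0 and 2 nm, exclusion distance 0.8 nm, ten
repeats of 10^6 pairs per plane:

```sh
kappa2sim run --mode weighted --theta-d 90 --sigma-d 0 --theta-a 90 --sigma-a 0 \
  --h1 0 --h2 2.0 --re1 0.8 --re2 0.8 --n 1000000 --repeats 10 --seed 1 --out out/
```

prints (abridged):

```json
{
  "mean_unweighted": 1.2398991436769118,
  "mean_weighted": 1.1572871542794023,
  "grand_mean": 1.2166754852418697,
  "std_dev": 0.0989949840007051
}
```

`mean_unweighted` is the plain histogram average over the seed-1 run
(close to the coplanar Knoester value 1.25 for this orientation);
`mean_weighted` is that run's distance-weighted average; `grand_mean` and
`std_dev` summarize the ten seeded repeats.  The weighted estimator is
dominated by near-contact pairs and therefore fluctuates noticeably from
run to run — the grand mean is the quantity to quote.  Histograms of
kappa^2 (pooled and per plane) and of both tilt angles are written as CSV
next to a JSON summary and a run manifest.

Bundled probe-pair presets (`kappa2sim preset list`) carry literature
transverse locations and orientation distributions for common membrane
probes (t-PnA, DPH, NBD, BODIPY, carbocyanine, Rhodamine B):

```sh
kappa2sim preset run tPnA_DPH --seed 1
```

Efficiency curves from the planar decay law:

```python
from kappa2sim import FretSystemSpec, efficiency
efficiency(FretSystemSpec.from_kappa2(alpha=0.5, kappa2_mean=1.25, sigma_c=2.0))
# 0.1039
efficiency(FretSystemSpec.from_kappa2(alpha=0.5, kappa2_mean=0.30, sigma_c=2.0))
# 0.0273
```

With the Förster radius comparable to the exclusion distance (alpha = 0.5),
the orientation factor alone changes the predicted efficiency almost
four-fold.

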