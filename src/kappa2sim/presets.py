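"""Catalogue of common membrane FRET probe pairs.

Each preset carries the transverse location (distance of the fluorophore
from the bilayer center, nm) and the orientation distribution (most
probable tilt from the membrane normal and cos-theta spread) of donor and
acceptor, as compiled from published linear-dichroism, quenching and
molecular-dynamics studies of the individual probes.  The bilayer geometry
follows from the transverse locations: with the donor in one leaflet at
depth z_D and acceptors in both leaflets at depth z_A, the donor faces one
acceptor plane at h1 = |z_D - z_A| (cis leaflet) and one at h2 = z_D + z_A
(trans leaflet).

Probe abbreviations: t-PnA, trans-parinaric acid; DPH, diphenylhexatriene;
NBD, 7-nitrobenz-2-oxa-1,3-diazol-4-yl (NBD-PC label); BODIPY,
4,4-difluoro-3a,4a-diaza-s-indacene; carbocyanine, DiI-type indocarbocyanine;
Rhodamine B (headgroup-labelled lipid).  The t-PnA/DPH pair is also
provided with the gel-phase t-PnA orientation (5 deg, 0.03), which is much
narrower than in the fluid phase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .orientation import AngularDistributionSpec
from .simulator import GeometryConfig, Kappa2Result, RepeatSummary, simulate_weighted

__all__ = ["ProbePairPreset", "preset_catalogue", "get_preset", "run_preset"]

# standard run parameters for preset simulations: two acceptor planes,
# 1/R^6 weighting, N = 1e6 pairs per plane, Re = 0.8 nm, l = 100 nm
PRESET_L = 100.0
PRESET_N_PAIRS = 1_000_000
PRESET_RE = 0.8
PRESET_REPEATS = 10


@dataclass(frozen=True)
class ProbePairPreset:
    """A named donor/acceptor pair with locations and orientation specs."""

    name: str
    donor_z: float
    acceptor_z: float
    donor_spec: AngularDistributionSpec
    acceptor_spec: AngularDistributionSpec

    def __post_init__(self) -> None:
        if self.donor_z < 0 or self.acceptor_z < 0:
            raise ValueError("transverse locations must be >= 0 nm")

    @property
    def h1(self) -> float:
        """Donor to same-leaflet acceptor plane distance, nm."""
        return abs(self.donor_z - self.acceptor_z)

    @property
    def h2(self) -> float:
        """Donor to opposite-leaflet acceptor plane distance, nm."""
        return self.donor_z + self.acceptor_z

    def geometry(self, n_pairs: int = PRESET_N_PAIRS, seed: int = 0,
                 n_bins: int = 100) -> GeometryConfig:
        """Two-plane weighted geometry with the standard run parameters."""
        return GeometryConfig(
            l=PRESET_L, n_pairs=n_pairs, h1=self.h1, h2=self.h2,
            re1=PRESET_RE, re2=PRESET_RE, n_bins=n_bins, seed=seed,
        )


# per-fluorophore (location nm, theta_max deg, sigma); each fluorophore's
# parameters are identical wherever it appears
_TPNA = (0.92, 20.0, 0.15)
_TPNA_GEL = (0.92, 5.0, 0.03)
_DPH = (0.75, 0.0, 0.35)
_NBD = (1.35, 125.0, 0.35)
_CARBOCYANINE = (1.26, 77.0, 0.25)
_RHODAMINE_B = (2.1, 90.0, 0.275)
_BODIPY = (0.8, 10.0, 0.5)


def _pair(name: str, donor, acceptor) -> ProbePairPreset:
    dz, dth, dsig = donor
    az, ath, asig = acceptor
    return ProbePairPreset(
        name=name,
        donor_z=dz,
        acceptor_z=az,
        donor_spec=AngularDistributionSpec(dth, dsig),
        acceptor_spec=AngularDistributionSpec(ath, asig),
    )


def preset_catalogue() -> list[ProbePairPreset]:
    """All bundled donor/acceptor presets."""
    return [
        _pair("tPnA_DPH", _TPNA, _DPH),
        _pair("DPH_NBD", _DPH, _NBD),
        _pair("NBD_NBD", _NBD, _NBD),
        _pair("NBD_carbocyanine", _NBD, _CARBOCYANINE),
        _pair("NBD_rhodamineB", _NBD, _RHODAMINE_B),
        _pair("BODIPY_rhodamineB", _BODIPY, _RHODAMINE_B),
        _pair("BODIPY_carbocyanine", _BODIPY, _CARBOCYANINE),
        _pair("rhodamineB_homo", _RHODAMINE_B, _RHODAMINE_B),
        _pair("tPnA_DPH_gel", _TPNA_GEL, _DPH),
    ]


def get_preset(name: str) -> ProbePairPreset:
    for p in preset_catalogue():
        if p.name == name:
            return p
    known = ", ".join(p.name for p in preset_catalogue())
    raise KeyError(f"unknown preset {name!r}; known presets: {known}")


def run_preset(
    name: str,
    n_repeats: int = PRESET_REPEATS,
    base_seed: int = 1,
    n_pairs: int = PRESET_N_PAIRS,
) -> tuple[RepeatSummary, Kappa2Result]:
    """Weighted two-plane <kappa^2> for a named preset, over repeated runs.

    Returns the repeat summary (grand mean and run-to-run standard
    deviation) together with the full result of the first run (histograms).
    """
    preset = get_preset(name)
    geom = preset.geometry(n_pairs=n_pairs, seed=base_seed)
    results = [
        simulate_weighted(preset.donor_spec, preset.acceptor_spec,
                          dataclasses.replace(geom, seed=base_seed + k))
        for k in range(n_repeats)
    ]
    means = [r.mean for r in results]
    arr = np.asarray(means)
    summary = RepeatSummary(
        means=means,
        grand_mean=float(arr.mean()),
        std_dev=float(arr.std(ddof=1)),
        n_repeats=n_repeats,
    )
    return summary, results[0]
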