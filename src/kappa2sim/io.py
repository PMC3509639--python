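"""Run configuration parsing and result writers.

Config files are YAML key-value mappings mirroring the CLI flags; unknown
keys and out-of-range values are rejected with the offending key named.
Results are written as a histogram CSV (bin_left, bin_right, density), a
JSON summary (means, spread, config echo) and a manifest listing every
file produced by the run.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .orientation import AngularDistributionSpec
from .simulator import GeometryConfig, Kappa2Result, RepeatSummary

__all__ = ["RunConfig", "load_config", "write_results"]

_MODES = ("unweighted", "slab", "weighted")


@dataclass
class RunConfig:
    """Validated full run configuration with defaults applied."""

    mode: str = "unweighted"
    theta_d_max_deg: float = 90.0
    theta_a_max_deg: float = 90.0
    sigma_d: float = 0.0
    sigma_a: float = 0.0
    l: float = 100.0
    n: int = 1_000_000
    h: float = 0.0
    h1: float | None = None
    h2: float | None = None
    re1: float | None = None
    re2: float | None = None
    slab_zmax: float | None = None
    bins: int = 100
    seed: int = 1
    repeats: int = 1
    normal_method: str = "box-muller"

    def donor_spec(self) -> AngularDistributionSpec:
        return AngularDistributionSpec(self.theta_d_max_deg, self.sigma_d)

    def acceptor_spec(self) -> AngularDistributionSpec:
        return AngularDistributionSpec(self.theta_a_max_deg, self.sigma_a)

    def geometry(self) -> GeometryConfig:
        re_default = 0.8 if self.mode == "weighted" else 0.0
        return GeometryConfig(
            l=self.l,
            n_pairs=self.n,
            h=self.h,
            h1=self.h1 if self.h1 is not None else (0.0 if self.mode == "weighted" else None),
            h2=self.h2,
            re1=self.re1 if self.re1 is not None else re_default,
            re2=self.re2 if self.re2 is not None else re_default,
            slab_zmax=self.slab_zmax,
            n_bins=self.bins,
            seed=self.seed,
            normal_method=self.normal_method,
        )


_RANGES: dict[str, tuple[float, float]] = {
    "theta_d_max_deg": (0.0, 180.0),
    "theta_a_max_deg": (0.0, 180.0),
    "sigma_d": (0.0, np.inf),
    "sigma_a": (0.0, np.inf),
    "l": (np.nextafter(0.0, 1.0), np.inf),
    "n": (1, np.inf),
    "h": (0.0, np.inf),
    "h1": (0.0, np.inf),
    "h2": (0.0, np.inf),
    "re1": (0.0, np.inf),
    "re2": (0.0, np.inf),
    "slab_zmax": (0.0, np.inf),
    "bins": (1, np.inf),
    "repeats": (1, np.inf),
}


class ConfigError(ValueError):
    """A config file failed validation."""


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults.  Unknown keys and values outside
    their admissible range raise :class:`ConfigError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path}: expected a key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config {path}: unknown keys {sorted(unknown)}")
    if "mode" in raw and raw["mode"] not in _MODES:
        raise ConfigError(f"config {path}: mode must be one of {_MODES}")
    for key, (lo, hi) in _RANGES.items():
        if key in raw and raw[key] is not None:
            v = raw[key]
            if not isinstance(v, (int, float)) or not lo <= v <= hi:
                raise ConfigError(
                    f"config {path}: key {key!r} value {v!r} outside [{lo}, {hi}]"
                )
    return RunConfig(**raw)


def _histogram_frame(edges: np.ndarray, density: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
    )


def write_results(
    result: Kappa2Result,
    out_dir: str | Path,
    stem: str = "kappa2",
    summary: RepeatSummary | None = None,
    config: dict[str, Any] | None = None,
) -> dict[str, str]:
    """Write histogram CSV, summary JSON and a run manifest.

    Returns the manifest mapping (artifact name -> path).  Content is
    deterministic for a fixed seed apart from the manifest timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    hist_path = out / f"{stem}_hist.csv"
    _histogram_frame(result.bin_edges, result.density).to_csv(hist_path, index=False)
    paths["histogram"] = str(hist_path)

    for i, dens in enumerate(result.plane_densities, start=1):
        p = out / f"{stem}_hist_plane{i}.csv"
        _histogram_frame(result.bin_edges, dens).to_csv(p, index=False)
        paths[f"histogram_plane{i}"] = str(p)

    for label, (edges, dens) in (
        ("theta_d", result.theta_d_hist),
        ("theta_a", result.theta_a_hist),
    ):
        p = out / f"{stem}_{label}_hist.csv"
        _histogram_frame(edges, dens).to_csv(p, index=False)
        paths[f"{label}_histogram"] = str(p)

    summary_obj: dict[str, Any] = {
        "mean_unweighted": result.mean_unweighted,
        "mean_weighted": result.mean_weighted,
        "max_kappa2": result.max_kappa2,
        "n_pairs": result.n_pairs,
        "seed": result.seed,
        "config": config or {},
    }
    if summary is not None:
        summary_obj["repeats"] = {
            "means": summary.means,
            "grand_mean": summary.grand_mean,
            "std_dev": summary.std_dev,
            "n_repeats": summary.n_repeats,
        }
    summary_path = out / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(summary_obj, indent=2))
    paths["summary"] = str(summary_path)

    manifest = {
        "software": f"kappa2sim {__version__}",
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": result.seed,
        "outputs": paths,
    }
    manifest_path = out / f"{stem}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(manifest_path)
    return paths
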