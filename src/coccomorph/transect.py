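"""Virtual west-east transect: environmental gradients and variety niches.

Emulates the sampling design of a Mediterranean-style basin crossing: a
line of stations spanning a longitude range, each sampled at several
photic-zone depths, with smooth environmental gradients (salinity,
alkalinity and temperature increasing eastward; pCO2 and nutrients
decreasing; light attenuating with depth) and coccolith calcification
varieties responding to those gradients through Gaussian niche curves.

The generator is the ground truth for every downstream statistic: the
configured niche signs are what the ecology module's Spearman/CCA results
must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shapes import (
    DEFAULT_VARIETY_PARAMS,
    VARIETY_LABELS,
    CoccolithShape,
    VarietyParams,
    sample_shape,
)

ENV_VARIABLES = (
    "temperature",
    "salinity",
    "total_alkalinity",
    "ph",
    "pco2",
    "carbonate_ion",
    "nitrate_nitrite",
    "phosphate",
    "par_percent",
)


@dataclass(frozen=True)
class EnvProfile:
    """Smooth profile of one variable along the transect.

    value(longitude, depth) =
        west + (east - west) * g(longitude) + depth_slope * depth
    where g is linear or a logistic ramp in normalized longitude, clipped
    to [lo, hi] if bounds are given.
    """

    west: float
    east: float
    kind: str = "linear"  # "linear" | "sigmoid"
    depth_slope: float = 0.0  # per meter
    bounds: tuple[float, float] | None = None
    noise_sd: float = 0.0

    def evaluate(self, lon_frac: np.ndarray, depth_m: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
        if self.kind == "linear":
            g = lon_frac
        elif self.kind == "sigmoid":
            g = 1.0 / (1.0 + np.exp(-8.0 * (lon_frac - 0.5)))
        else:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        v = self.west + (self.east - self.west) * g + self.depth_slope * depth_m
        if self.noise_sd > 0:
            v = v + rng.normal(0.0, self.noise_sd, size=np.shape(v))
        if self.bounds is not None:
            v = np.clip(v, *self.bounds)
        return v


# Gradients patterned on a west-to-east Mediterranean crossing in late
# spring: the eastern basin is saltier, warmer, more alkaline and more
# oligotrophic than the Atlantic inflow.
DEFAULT_ENV_PROFILES: Mapping[str, EnvProfile] = {
    "temperature": EnvProfile(16.0, 21.0, "linear", depth_slope=-0.04, noise_sd=0.3),
    "salinity": EnvProfile(36.3, 39.2, "sigmoid", noise_sd=0.05),
    "total_alkalinity": EnvProfile(2400.0, 2630.0, "linear", noise_sd=5.0),
    "ph": EnvProfile(8.05, 8.10, "linear", noise_sd=0.005),
    "pco2": EnvProfile(420.0, 360.0, "linear", noise_sd=5.0),
    "carbonate_ion": EnvProfile(215.0, 260.0, "linear", noise_sd=3.0),
    "nitrate_nitrite": EnvProfile(2.5, 0.3, "linear", bounds=(0.0, math.inf),
                                  noise_sd=0.1),
    "phosphate": EnvProfile(0.12, 0.02, "linear", bounds=(0.0, math.inf),
                            noise_sd=0.005),
    # percent of surface photosynthetically active radiation, e-folding ~35 m
    "par_percent": EnvProfile(100.0, 100.0, "linear", bounds=(0.0, 100.0)),
}

PAR_EFOLDING_M = 35.0


@dataclass(frozen=True)
class NicheResponse:
    """Gaussian niche of one variety on standardized environmental axes.

    ``responses`` maps environment variable name -> (optimum, tolerance)
    in standard-deviation units of that variable across the transect;
    ``max_abundance`` is the niche height (relative units).
    """

    max_abundance: float
    responses: Mapping[str, tuple[float, float]]

    def score(self, env_z: pd.DataFrame) -> np.ndarray:
        s = np.full(len(env_z), self.max_abundance, dtype=float)
        for var, (opt, tol) in self.responses.items():
            if var not in env_z.columns:
                raise KeyError(
                    f"niche references unknown environmental variable {var!r}"
                )
            if tol <= 0:
                raise ValueError(f"niche tolerance for {var!r} must be > 0")
            z = env_z[var].to_numpy()
            s = s * np.exp(-0.5 * ((z - opt) / tol) ** 2)
        return s


# Niche signs mirror the field pattern: the lightly calcified A1 prefers
# the fresher western surface waters, A3b the salty eastern mid-photic
# zone, A3a colder western waters, and B/C the Atlantic inflow.
DEFAULT_VARIETY_NICHES: Mapping[str, NicheResponse] = {
    "A1": NicheResponse(1.0, {"salinity": (-1.2, 1.2), "par_percent": (1.0, 1.5)}),
    "A2": NicheResponse(1.1, {"salinity": (0.2, 2.5)}),
    "A3a": NicheResponse(0.35, {"temperature": (-1.6, 0.9)}),
    "A3b": NicheResponse(0.6, {"salinity": (1.5, 1.0), "par_percent": (-1.0, 1.5)}),
    "BC": NicheResponse(0.25, {"salinity": (-2.0, 0.8)}),
}


@dataclass(frozen=True)
class TransectConfig:
    n_stations: int = 12
    depths: Sequence[float] = (5.0, 40.0, 100.0)
    lon_west: float = -5.5
    lon_east: float = 33.0
    env_profiles: Mapping[str, EnvProfile] = field(
        default_factory=lambda: dict(DEFAULT_ENV_PROFILES)
    )
    variety_niches: Mapping[str, NicheResponse] = field(
        default_factory=lambda: dict(DEFAULT_VARIETY_NICHES)
    )
    variety_params: Mapping[str, VarietyParams] = field(
        default_factory=lambda: dict(DEFAULT_VARIETY_PARAMS)
    )
    coccoliths_per_sample: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 0:
            raise ValueError("n_stations must be >= 0")
        if self.coccoliths_per_sample <= 0:
            raise ValueError("coccoliths_per_sample must be > 0")
        unknown = set(self.env_profiles) - set(ENV_VARIABLES)
        if unknown:
            raise KeyError(f"unknown environmental variables: {sorted(unknown)}")
        for v in self.variety_niches:
            if v not in VARIETY_LABELS:
                raise ValueError(f"niche for unknown variety {v!r}")


def generate_environment(config: TransectConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Environment table: one row per (station, depth) sample."""
    lons = np.linspace(config.lon_west, config.lon_east,
                       max(config.n_stations, 1))[: config.n_stations]
    records = []
    for i, lon in enumerate(lons):
        frac = (lon - config.lon_west) / max(config.lon_east - config.lon_west, 1e-9)
        for depth in config.depths:
            row = {"station": i + 1, "longitude_E": float(lon),
                   "depth_m": float(depth)}
            for var in ENV_VARIABLES:
                prof = config.env_profiles[var]
                val = float(prof.evaluate(np.asarray(frac), np.asarray(depth), rng))
                if var == "par_percent":
                    val = float(np.clip(val * math.exp(-depth / PAR_EFOLDING_M),
                                        0.0, 100.0))
                row[var] = val
            records.append(row)
    cols = ["station", "longitude_E", "depth_m", *ENV_VARIABLES]
    return pd.DataFrame(records, columns=cols)


def _standardize(env: pd.DataFrame) -> pd.DataFrame:
    z = env[list(ENV_VARIABLES)].astype(float)
    sd = z.std(ddof=0).replace(0.0, 1.0)
    return (z - z.mean()) / sd


def generate_transect(
    config: TransectConfig | None = None,
) -> tuple[dict[tuple[int, float], list[CoccolithShape]], pd.DataFrame]:
    """Generate per-sample coccolith sets and the environment table.

    Variety counts in each sample are multinomial with probabilities
    proportional to the configured niche scores evaluated on the sample's
    standardized environment; individual coccoliths are then drawn from
    the per-variety shape distributions.  Fully deterministic for a fixed
    config (the seed lives in the config).

    Returns
    -------
    (samples, env):
        ``samples`` maps (station, depth_m) -> list of CoccolithShape;
        ``env`` is the environment table with one row per sample.
    """
    if config is None:
        config = TransectConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    env = generate_environment(config, rng)
    samples: dict[tuple[int, float], list[CoccolithShape]] = {}
    if env.empty:
        return samples, env

    env_z = _standardize(env)
    varieties = list(config.variety_niches)
    scores = np.column_stack(
        [config.variety_niches[v].score(env_z) for v in varieties]
    )

    for i, (_, row) in enumerate(env.iterrows()):
        p = scores[i]
        total = p.sum()
        if total <= 0:
            p = np.full(len(varieties), 1.0 / len(varieties))
        else:
            p = p / total
        counts = rng.multinomial(config.coccoliths_per_sample, p)
        shapes: list[CoccolithShape] = []
        for v, n in zip(varieties, counts):
            params = config.variety_params[v]
            shapes.extend(sample_shape(v, params, rng) for _ in range(n))
        samples[(int(row["station"]), float(row["depth_m"]))] = shapes
    return samples, env


def variety_fractions(samples: Mapping[tuple[int, float], list[CoccolithShape]],
                      ) -> pd.DataFrame:
    """True per-sample variety percentages (of Type A) from generator labels."""
    rows = []
    for (station, depth), shapes in samples.items():
        labels = [s.variety_label for s in shapes]
        n_a = sum(1 for l in labels if l != "BC")
        row = {"station": station, "depth_m": depth, "n_typeA": n_a,
               "typeA_percent": 100.0 * n_a / len(labels) if labels else np.nan}
        for v in ("A1", "A2", "A3a", "A3b"):
            row[f"{v}_pct"] = (100.0 * labels.count(v) / n_a) if n_a else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
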