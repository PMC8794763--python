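"""Synthetic survey-series generator.

Emulates the three annual series the analysis consumes — breeding-population
abundance, May pond counts, and per-class harvest rates — under any of the
candidate generating processes, so the full forecasting pipeline is testable
end to end without the real survey downloads.

The defaults describe the study conditions (see docs/methods.md): a 48-year
record (1972-2019) whose last 24 years form the evaluation window, initial
abundance 8 million birds, lognormal process noise with log-sd 0.05,
lognormal AR(1) ponds around 4 million, truncated-normal harvest rates, and
multiplicative lognormal observation noise with CV 0.05.

Latent dynamics by generator id:

    SaRw/SaRs/ScRw/ScRs : balance-equation step x exp(eps)
    persistence         : N x exp(eps)                    (driftless walk)
    wetland             : N x exp(beta * W_std + eps)

eps ~ Normal(0, process_sd^2). The wetland covariate applied by the
generator is the full-series standardization of the emitted pond series
(sample sd), so it can be reconstructed exactly from the output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .ahm_models import (AHM_MODEL_IDS, AHMParams, balance_step, class_survival,
                         default_params, reproduction_rate)
from .null_models import PERSISTENCE_ID, WETLAND_ID
from .series_io import (HARVEST_CLASSES, AbundanceSeries, HarvestSeries,
                        WetlandSeries, standardize_wetlands, write_series)

__all__ = ["ScenarioSpec", "SimulationBundle", "simulate_wetlands", "simulate_population", "write_bundle"]

GENERATOR_IDS = AHM_MODEL_IDS + (PERSISTENCE_ID, WETLAND_ID)
LATENT_BOUNDS = (1e-3, 1e3)  # millions; outside means the parameterization is unstable


@dataclass
class ScenarioSpec:
    """Complete description of one synthetic study."""

    generator: str = "SaRw"
    n_years: int = 48
    start_year: int = 1972
    n0: float = 8.0                   # initial latent abundance, millions
    process_sd: float = 0.05          # log-scale process noise sd
    beta: float = 0.1                 # wetland-null growth effect per z-unit
    wetland_mean: float = 4.0         # millions of ponds (median of the AR(1))
    wetland_phi: float = 0.5          # lag-1 autocorrelation on the log scale
    wetland_sd: float = 0.25          # AR(1) innovation sd, log scale
    harvest_mean: Mapping[str, float] = field(
        default_factory=lambda: {"am": 0.14, "af": 0.09, "jm": 0.18, "jf": 0.12})
    harvest_sd: float = 0.03
    harvest_bounds: tuple[float, float] = (0.01, 0.35)
    obs_cv: float = 0.05              # survey observation noise, CV
    obs_mode: str = "lognormal"       # or "normal" (additive, sd = cv * latent)
    ahm_params: AHMParams = field(default_factory=default_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in GENERATOR_IDS:
            raise ValueError(f"unknown generator {self.generator!r}; expected one of {GENERATOR_IDS}")
        if self.n_years < 5:
            raise ValueError("n_years must be >= 5")
        if self.n0 <= 0:
            raise ValueError("initial abundance must be positive")
        if not abs(self.wetland_phi) < 1:
            raise ValueError(f"wetland autocorrelation phi must satisfy |phi| < 1, got {self.wetland_phi}")
        for name in ("process_sd", "wetland_sd", "harvest_sd", "obs_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.harvest_bounds
        if not (0 <= lo < hi < 1):
            raise ValueError(f"harvest bounds must satisfy 0 <= lo < hi < 1, got {self.harvest_bounds}")
        if set(self.harvest_mean) != set(HARVEST_CLASSES):
            raise ValueError(f"harvest_mean must cover classes {HARVEST_CLASSES}")
        if self.obs_mode not in ("lognormal", "normal"):
            raise ValueError(f"unknown obs_mode {self.obs_mode!r}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def truth_dict(self) -> dict:
        d = asdict(self)
        d["harvest_mean"] = dict(self.harvest_mean)
        d["harvest_bounds"] = list(self.harvest_bounds)
        return d


@dataclass(frozen=True)
class SimulationBundle:
    latent: AbundanceSeries
    observed: AbundanceSeries
    wetlands: WetlandSeries
    harvest: HarvestSeries
    spec: ScenarioSpec


def simulate_wetlands(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> WetlandSeries:
    """Stationary AR(1) on log pond counts, exponentiated.

    The process is started from its stationary distribution, so the whole
    series is stationary; with innovation sd 0 the series is constant at
    ``wetland_mean``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    phi, sd = spec.wetland_phi, spec.wetland_sd
    mu = math.log(spec.wetland_mean)
    x = np.empty(spec.n_years)
    stat_sd = sd / math.sqrt(1.0 - phi**2) if sd > 0 else 0.0
    x[0] = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
    innov = rng.normal(0.0, sd, size=spec.n_years - 1) if sd > 0 else np.zeros(spec.n_years - 1)
    for t in range(1, spec.n_years):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return WetlandSeries(spec.years, np.exp(mu + x))


def _simulate_harvest(spec: ScenarioSpec, rng: np.random.Generator) -> HarvestSeries:
    lo, hi = spec.harvest_bounds
    k = {}
    for cls in HARVEST_CLASSES:
        m = spec.harvest_mean[cls]
        if spec.harvest_sd == 0:
            k[cls] = np.full(spec.n_years, float(np.clip(m, lo, hi)))
        else:
            a, b = (lo - m) / spec.harvest_sd, (hi - m) / spec.harvest_sd
            k[cls] = stats.truncnorm.rvs(a, b, loc=m, scale=spec.harvest_sd,
                                         size=spec.n_years, random_state=rng)
    return HarvestSeries(spec.years, k)


def simulate_population(spec: ScenarioSpec) -> SimulationBundle:
    """Latent dynamics under the chosen generator, plus noisy survey observations.

    Deterministic given the spec (including its seed). Raises, naming the
    year, if the latent trajectory leaves ``LATENT_BOUNDS``.
    """
    rng = np.random.default_rng(spec.seed)
    wetlands = simulate_wetlands(spec, rng)
    harvest = _simulate_harvest(spec, rng)
    w_std = standardize_wetlands(wetlands, baseline="full")

    n = np.empty(spec.n_years)
    n[0] = spec.n0
    eps = (rng.normal(0.0, spec.process_sd, size=spec.n_years - 1)
           if spec.process_sd > 0 else np.zeros(spec.n_years - 1))
    for t in range(spec.n_years - 1):
        year = int(spec.years[t])
        if spec.generator in AHM_MODEL_IDS:
            form = "additive" if spec.generator.startswith("Sa") else "compensatory"
            s = class_survival(spec.ahm_params.survival, harvest.rates_at(year), form)
            r = reproduction_rate(spec.ahm_params.repro(spec.generator), n[t],
                                  w_std.value_at(year))
            det = balance_step(spec.ahm_params.balance, n[t], s, r)
        elif spec.generator == PERSISTENCE_ID:
            det = n[t]
        else:  # wetland null
            det = n[t] * math.exp(spec.beta * w_std.value_at(year))
        n[t + 1] = det * math.exp(eps[t])
        if not (LATENT_BOUNDS[0] < n[t + 1] < LATENT_BOUNDS[1]):
            raise ValueError(
                f"latent abundance {n[t + 1]:.3g} out of bounds at year {year + 1}; "
                "parameterization unstable")

    latent = AbundanceSeries(spec.years, n)
    if spec.obs_cv == 0:
        observed = AbundanceSeries(spec.years, n.copy(), None)
    elif spec.obs_mode == "lognormal":
        sigma_obs = math.sqrt(math.log1p(spec.obs_cv**2))
        obs = n * np.exp(rng.normal(0.0, sigma_obs, size=spec.n_years))
        observed = AbundanceSeries(spec.years, obs, spec.obs_cv * obs)
    else:
        obs = n + rng.normal(0.0, spec.obs_cv * n)
        if np.any(obs <= 0):
            raise ValueError("additive observation noise produced nonpositive abundance")
        observed = AbundanceSeries(spec.years, obs, spec.obs_cv * obs)
    return SimulationBundle(latent, observed, wetlands, harvest, spec)


def write_bundle(bundle: SimulationBundle, outdir: str | Path) -> list[Path]:
    """Emit abundance.csv, wetlands.csv, harvest.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.csv",
        "wetlands": outdir / "wetlands.csv",
        "harvest": outdir / "harvest.csv",
    }
    write_series(bundle.observed, paths["abundance"])
    write_series(bundle.wetlands, paths["wetlands"])
    write_series(bundle.harvest, paths["harvest"])
    truth = bundle.spec.truth_dict()
    truth["ahm_params"] = {
        "survival": {"s0": dict(bundle.spec.ahm_params.survival.s0), "c": bundle.spec.ahm_params.survival.c},
        "repro_weak": asdict(bundle.spec.ahm_params.repro_weak),
        "repro_strong": asdict(bundle.spec.ahm_params.repro_strong),
        "balance": asdict(bundle.spec.ahm_params.balance),
    }
    truth["latent_n"] = bundle.latent.n.tolist()
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return [*paths.values(), truth_path]
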