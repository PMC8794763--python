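"""Expanding-window one-step-ahead forecast evaluation.

For every target year y in the evaluation window, each registered model is
given the data through year y-1 only (strict no-look-ahead) and produces a
predictive distribution for year y. Wetland standardization is recomputed
from the truncated history (recursive mode, the default) so no future pond
counts leak into a forecast either.

The weighted model average uses the weights available at the *start* of the
target year, i.e. the posterior through year y-1 — the forecast a manager
could actually have issued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import null_models
from .ahm_models import AHM_MODEL_IDS, AHMParams, ahm_forecast, default_params
from .null_models import NIGPrior, fit_wetland_model, persistence_forecast, wetland_forecast
from .records import ForecastRecord
from .series_io import (AbundanceSeries, HarvestSeries, WetlandSeries,
                        standardize_wetlands)
from .weights import ModelWeights, WeightSeries, init_weights, weight_trajectory

__all__ = ["ForecastTable", "run_one_step_ahead", "model_average", "model_averaged_forecasts"]

logger = logging.getLogger(__name__)

AVERAGE_ID = "avg"
KNOWN_MODELS = AHM_MODEL_IDS + (null_models.PERSISTENCE_ID, null_models.WETLAND_ID)


@dataclass
class ForecastTable:
    """Forecast records keyed by (model_id, target_year) plus aligned observations."""

    records: dict[tuple[str, int], ForecastRecord] = field(default_factory=dict)
    observed: dict[int, float] = field(default_factory=dict)

    def add(self, rec: ForecastRecord) -> None:
        key = (rec.model_id, rec.target_year)
        if key in self.records:
            raise ValueError(f"duplicate forecast for {key}")
        self.records[key] = rec

    def get(self, model_id: str, year: int) -> ForecastRecord:
        return self.records[(model_id, year)]

    def models(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for mid, _ in self.records:
            seen.setdefault(mid)
        return tuple(seen)

    def years_for(self, model_id: str) -> list[int]:
        return sorted(y for m, y in self.records if m == model_id)

    def common_years(self, model_ids: Sequence[str] | None = None) -> list[int]:
        """Years where every listed model has a forecast and an observation exists."""
        ids = list(model_ids) if model_ids is not None else list(self.models())
        if not ids:
            return []
        sets = [set(self.years_for(m)) for m in ids]
        years = set.intersection(*sets) & set(self.observed)
        return sorted(years)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (mid, year), rec in sorted(self.records.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            rows.append({
                "model_id": mid,
                "target_year": year,
                "mean": rec.mean,
                "sd": rec.sd,
                "family": rec.family,
                "observed": self.observed.get(year),
            })
        return pd.DataFrame(rows)


def run_one_step_ahead(abundance: AbundanceSeries,
                       wetlands: WetlandSeries,
                       harvest: HarvestSeries,
                       models: Sequence[str],
                       eval_years: tuple[int, int],
                       ahm_params: AHMParams | None = None,
                       prior: NIGPrior | None = None,
                       standardization: str = "recursive",
                       use_obs_se: bool = True) -> ForecastTable:
    """Produce one forecast per model per target year in ``eval_years``.

    A target year is skipped (and logged) when it or its predecessor has no
    observation — forecasts are never interpolated across survey gaps. The
    wetland null model falls back to a persistence-style forecast until it
    has three growth observations.
    """
    ahm_params = ahm_params or default_params()
    unknown = set(models) - set(KNOWN_MODELS)
    if unknown:
        raise ValueError(f"unknown model id(s) {sorted(unknown)}; known: {KNOWN_MODELS}")
    first, last = eval_years
    if first > last:
        raise ValueError("evaluation window is empty")
    if first <= int(abundance.years[0]):
        raise ValueError("evaluation must start after the first data year")

    table = ForecastTable()
    obs_years = set(int(y) for y in abundance.years)
    for y in range(first, last + 1):
        if y in obs_years:
            table.observed[y] = abundance.value_at(y)

    for y in range(first, last + 1):
        if y not in obs_years or (y - 1) not in obs_years:
            logger.info("skipping target year %d: survey gap", y)
            continue
        hist_n = abundance.truncate(y - 1)
        hist_w = wetlands.truncate(y - 1)
        w_std = standardize_wetlands(hist_w, baseline=standardization)
        n_prev = hist_n.value_at(y - 1)
        w_prev = w_std.value_at(y - 1)
        se_prev = hist_n.se_at(y - 1) if use_obs_se else None

        for mid in models:
            if mid in AHM_MODEL_IDS:
                rates = harvest.rates_at(y - 1)
                rec = ahm_forecast(mid, y - 1, n_prev, w_prev, rates, ahm_params, obs_se=se_prev)
            elif mid == null_models.PERSISTENCE_ID:
                rec = persistence_forecast(hist_n)
            else:  # wetland null, with persistence fallback at series start
                x, _ = null_models.growth_observations(hist_n, w_std)
                if len(x) < 3:
                    base = persistence_forecast(hist_n)
                    rec = ForecastRecord(null_models.WETLAND_ID, base.target_year, base.mean,
                                         base.sd, "normal", {**base.params, "fallback": True})
                else:
                    post = fit_wetland_model(hist_n, w_std, prior)
                    rec = wetland_forecast(post, n_prev, w_prev, y - 1)
            table.add(rec)
    return table


def model_average(records: Iterable[ForecastRecord], weights: ModelWeights,
                  model_id: str = AVERAGE_ID) -> ForecastRecord:
    """Mixture forecast over one year's records under the given weights.

    mean = sum w_i mean_i;  var = sum w_i (sd_i^2 + mean_i^2) - mean^2.
    """
    recs = {r.model_id: r for r in records}
    if set(recs) != set(weights.model_ids):
        raise ValueError(f"weights cover {sorted(weights.model_ids)} but records cover {sorted(recs)}")
    years = {r.target_year for r in recs.values()}
    if len(years) != 1:
        raise ValueError(f"records span multiple target years: {sorted(years)}")
    (year,) = years
    mean = sum(weights[m] * recs[m].mean for m in recs)
    # within + between variance (stable form of sum w(sd^2+mean^2) - mean^2)
    var = sum(weights[m] * (recs[m].sd**2 + (recs[m].mean - mean) ** 2) for m in recs)
    comps = [(weights[m], recs[m]) for m in recs]
    return ForecastRecord(model_id, year, mean, var**0.5, "mixture", {"components": comps})


def model_averaged_forecasts(table: ForecastTable,
                             weighted_models: Sequence[str] = AHM_MODEL_IDS,
                             initial: ModelWeights | None = None,
                             ) -> tuple[ForecastTable, WeightSeries]:
    """Add start-of-year weighted-average records; return the weight series too.

    Weights for target year y are the posterior through year y-1; the update
    for year y happens only after its observation, mirroring the annual
    monitoring-forecast-update cycle.
    """
    initial = initial or init_weights(weighted_models)
    series = weight_trajectory(table, initial)
    out = ForecastTable(records=dict(table.records), observed=dict(table.observed))
    for y in table.common_years(list(weighted_models)):
        recs = [table.get(m, y) for m in weighted_models]
        out.add(model_average(recs, series.before(y)))
    return out, series
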