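"""Bayesian model-weight updating from one-step-ahead forecast likelihoods.

Each year, every candidate model's predictive density is evaluated at the
newly observed abundance and the weights are updated by Bayes' theorem:

    w_i' = w_i * f_i(obs) / sum_j w_j * f_j(obs)

Updates accumulate in log space; sequential yearly updates are algebraically
identical to a single batch update with the product of densities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .records import ForecastRecord, record_logpdf

__all__ = ["ModelWeights", "WeightSeries", "init_weights", "update_weights", "weight_trajectory"]

logger = logging.getLogger(__name__)

#: |obs - mean| tolerance under which a degenerate (sd = 0) forecast is
#: treated as a point mass that hits the observation.
POINT_MASS_TOL = 1e-9


@dataclass(frozen=True)
class ModelWeights:
    """Per-model probability vector at a point in time (after observing `year`)."""

    year: int | None
    w: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.w:
            raise ValueError("empty weight vector")
        vals = np.array(list(self.w.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {vals.sum():.15f}")

    def __getitem__(self, model_id: str) -> float:
        return self.w[model_id]

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(self.w)

    def argmax(self) -> str:
        return max(self.w, key=lambda k: self.w[k])


@dataclass(frozen=True)
class WeightSeries:
    """Initial weights plus the post-update weights after each scored year."""

    initial: ModelWeights
    by_year: tuple[ModelWeights, ...]

    def before(self, year: int) -> ModelWeights:
        """Weights available at the start of `year` (posterior through year-1)."""
        current = self.initial
        for mw in self.by_year:
            if mw.year is not None and mw.year < year:
                current = mw
        return current

    @property
    def final(self) -> ModelWeights:
        return self.by_year[-1] if self.by_year else self.initial


def init_weights(model_ids: Sequence[str], year: int | None = None) -> ModelWeights:
    """Uniform prior 1/k over the candidate set (complete structural uncertainty)."""
    ids = list(model_ids)
    if not ids:
        raise ValueError("at least one model is required")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids")
    return ModelWeights(year=year, w={m: 1.0 / len(ids) for m in ids})


def _log_likelihood(rec: ForecastRecord, obs: float) -> float:
    if rec.sd == 0 or rec.params.get("sigma") == 0 or rec.params.get("scale") == 0:
        hit = abs(obs - rec.mean) < POINT_MASS_TOL
        logger.warning("degenerate sd=0 forecast for %s year %s treated as point mass (%s)",
                       rec.model_id, rec.target_year, "hit" if hit else "miss")
        return 0.0 if hit else -math.inf
    return record_logpdf(rec, obs)


def update_weights(w: ModelWeights, forecasts: Iterable[ForecastRecord], obs: float) -> ModelWeights:
    """One Bayes step from the forecasts for a single year and its observation."""
    recs = {r.model_id: r for r in forecasts}
    if set(recs) != set(w.model_ids):
        raise ValueError(f"forecast models {sorted(recs)} do not match weighted models {sorted(w.model_ids)}")
    years = {r.target_year for r in recs.values()}
    if len(years) != 1:
        raise ValueError(f"forecasts span multiple target years: {sorted(years)}")
    (year,) = years

    ids = list(w.model_ids)
    logpost = np.array([
        (math.log(w[m]) if w[m] > 0 else -math.inf) + _log_likelihood(recs[m], obs)
        for m in ids
    ])
    total = logsumexp(logpost)
    if not np.isfinite(total):
        raise ValueError(
            f"all model likelihoods vanished at year {year} (obs={obs}); "
            "check forecast distributions and observation scale")
    post = np.exp(logpost - total)
    post /= post.sum()
    return ModelWeights(year=year, w=dict(zip(ids, post)))


def weight_trajectory(table, init: ModelWeights) -> WeightSeries:
    """Sequential yearly updates over every scored year of a forecast table.

    `table` is a :class:`~ahmbench.harness.ForecastTable`; scored years are
    those where every weighted model has a forecast and an observation
    exists, taken in year order.
    """
    years = table.common_years(init.model_ids)
    current = init
    out = []
    for y in years:
        recs = [table.get(m, y) for m in init.model_ids]
        current = update_weights(current, recs, table.observed[y])
        out.append(current)
    return WeightSeries(initial=init, by_year=tuple(out))
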