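"""Forecast records: one model's predictive distribution for one target year.

A :class:`ForecastRecord` always carries a mean and sd on the abundance
scale (millions of birds) so point-forecast skill scores can be computed
uniformly, plus the full distributional family and its parameters so
predictive densities can be evaluated for Bayesian weight updating.

Families
--------
``normal``
    params ``{"mu", "sigma"}`` on the abundance scale (the stochastic
    persistence model's additive-noise form).
``lognormal``
    params ``{"mu", "sigma"}`` of log abundance (the mechanistic models'
    multiplicative process noise).
``student-t``
    params ``{"loc", "scale", "df"}`` of *log* abundance (the wetland
    null's posterior predictive, which carries parameter uncertainty).
    The stored mean/sd are moment-matched through a normal approximation
    to the t, since exp of a t variate has no finite moments.
``mixture``
    params ``{"components": [(weight, ForecastRecord), ...]}`` — the
    model-averaged forecast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["ForecastRecord", "lognormal_record", "record_pdf", "record_logpdf", "record_median"]


@dataclass(frozen=True)
class ForecastRecord:
    model_id: str
    target_year: int
    mean: float
    sd: float
    family: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"forecast sd must be >= 0, got {self.sd}")
        if self.family in ("lognormal", "student-t") and self.mean <= 0:
            raise ValueError(f"abundance-scale forecast mean must be > 0, got {self.mean}")
        if self.family not in ("normal", "lognormal", "student-t", "mixture"):
            raise ValueError(f"unknown forecast family {self.family!r}")


def lognormal_record(model_id: str, target_year: int, median: float, sigma_log: float,
                     **extra: Any) -> ForecastRecord:
    """Build a lognormal record from its median and log-scale sd.

    The stored mean/sd are the exact lognormal moments:
    ``E = median * exp(sigma^2/2)``, ``Var = E^2 * (exp(sigma^2) - 1)``.
    """
    if median <= 0:
        raise ValueError(f"lognormal median must be positive, got {median}")
    if sigma_log < 0:
        raise ValueError(f"log-scale sd must be >= 0, got {sigma_log}")
    mu = math.log(median)
    mean = median * math.exp(0.5 * sigma_log**2)
    sd = mean * math.sqrt(math.expm1(sigma_log**2))
    params = {"mu": mu, "sigma": sigma_log, **extra}
    return ForecastRecord(model_id, target_year, mean, sd, "lognormal", params)


def _t_log_params(params: Mapping[str, Any]) -> tuple[float, float, float]:
    return float(params["loc"]), float(params["scale"]), float(params["df"])


def t_log_moments(loc: float, scale: float, df: float) -> tuple[float, float]:
    """Moment-matched (mean, sd) on the abundance scale for exp(t).

    The log-scale t is approximated by a normal with the same location and
    variance ``scale^2 * df/(df-2)`` (for df <= 2, where the t variance
    diverges, the scale itself is used), then lognormal moments are taken.
    """
    var_log = scale**2 * (df / (df - 2.0) if df > 2.0 else 1.0)
    mean = math.exp(loc + 0.5 * var_log)
    sd = mean * math.sqrt(math.expm1(var_log))
    return mean, sd


def record_logpdf(rec: ForecastRecord, x: float) -> float:
    """Log predictive density of ``rec`` at observed abundance ``x``.

    Degenerate (sd == 0) records are the caller's responsibility; here they
    raise so silent point-mass evaluation cannot slip through.
    """
    if rec.family == "normal":
        if rec.sd == 0:
            raise ValueError("degenerate normal record: sd == 0")
        return float(stats.norm.logpdf(x, loc=rec.mean, scale=rec.sd))
    if rec.family == "lognormal":
        sigma = float(rec.params["sigma"])
        if sigma == 0:
            raise ValueError("degenerate lognormal record: sigma == 0")
        if x <= 0:
            return -math.inf
        mu = float(rec.params["mu"])
        return float(stats.norm.logpdf(math.log(x), loc=mu, scale=sigma) - math.log(x))
    if rec.family == "student-t":
        loc, scale, df = _t_log_params(rec.params)
        if scale == 0:
            raise ValueError("degenerate student-t record: scale == 0")
        if x <= 0:
            return -math.inf
        z = (math.log(x) - loc) / scale
        return float(stats.t.logpdf(z, df) - math.log(scale) - math.log(x))
    if rec.family == "mixture":
        comps: Sequence[tuple[float, ForecastRecord]] = rec.params["components"]
        logs = [math.log(w) + record_logpdf(r, x) for w, r in comps if w > 0]
        return float(np.logaddexp.reduce(logs))
    raise ValueError(f"unknown family {rec.family!r}")


def record_pdf(rec: ForecastRecord, x: float) -> float:
    return math.exp(record_logpdf(rec, x))


def record_median(rec: ForecastRecord) -> float:
    """Predictive median on the abundance scale (exact for every non-mixture family)."""
    if rec.family == "normal":
        return rec.mean
    if rec.family == "lognormal":
        return math.exp(float(rec.params["mu"]))
    if rec.family == "student-t":
        loc, _, _ = _t_log_params(rec.params)
        return math.exp(loc)
    raise ValueError(f"median not defined for family {rec.family!r}")
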