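"""Ecological null models: population persistence and wetland-driven growth.

Both are pattern-preserving benchmarks devoid of the vital-rate mechanisms
in the mechanistic models.

Persistence
    N_{t+1} = N_t + eps_t,  eps_t ~ Normal(0, sigma^2). The point forecast
    is the last observation; sigma is estimated as the sample sd of the
    one-step differences in the history (natural scale, matching the
    additive noise form).

Wetland model
    N_{t+1} = lambda_t * N_t with log(lambda_t) = r_eq + beta * W_t + eps_t,
    r_eq fixed at 0 (growth balances at equilibrium) and W_t the
    standardized pond count. beta and sigma^2 are estimated recursively
    (expanding window) by conjugate Bayesian linear regression through the
    origin with a normal--inverse-gamma prior, so the posterior predictive
    for log N_{t+1} is Student-t and carries parameter uncertainty into
    scoring and weight updating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import ForecastRecord, t_log_moments
from .series_io import AbundanceSeries, StandardizedWetlandSeries

__all__ = [
    "PersistenceState",
    "NIGPrior",
    "WetlandModelPosterior",
    "persistence_forecast",
    "fit_wetland_model",
    "wetland_forecast",
    "growth_observations",
]

PERSISTENCE_ID = "persistence"
WETLAND_ID = "wetland"


@dataclass(frozen=True)
class PersistenceState:
    sigma_hat: float  # sd of one-step differences, millions
    n_diffs: int

    def __post_init__(self) -> None:
        if self.sigma_hat < 0 or self.n_diffs < 1:
            raise ValueError("invalid persistence state")


def persistence_forecast(history: AbundanceSeries) -> ForecastRecord:
    """Forecast for the year after the last observation: mean N_t exactly.

    The predictive sd is the sample sd of all consecutive-year differences
    in the history (a single difference contributes its absolute value).
    """
    if len(history) < 2:
        raise ValueError("persistence forecast needs >= 2 years of history")
    consec = np.diff(history.years) == 1
    diffs = np.diff(history.n)[consec]
    if len(diffs) == 0:
        raise ValueError("no consecutive-year differences in history")
    sigma = abs(float(diffs[0])) if len(diffs) == 1 else float(np.std(diffs, ddof=1))
    n_t = float(history.n[-1])
    state = PersistenceState(sigma_hat=sigma, n_diffs=len(diffs))
    return ForecastRecord(PERSISTENCE_ID, int(history.years[-1]) + 1, n_t, sigma,
                          "normal", {"mu": n_t, "sigma": sigma, "n_diffs": state.n_diffs})


@dataclass(frozen=True)
class NIGPrior:
    """Normal--inverse-gamma prior: beta|s2 ~ N(m0, s2*v0), s2 ~ IG(a0, b0)."""

    m0: float = 0.0
    v0: float = 100.0
    a0: float = 0.01
    b0: float = 0.01

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("prior scale parameters must be positive")


@dataclass(frozen=True)
class WetlandModelPosterior:
    """Conjugate posterior over (beta, sigma^2) of the wetland growth model."""

    m: float   # posterior mean of beta
    v: float   # posterior scale: beta|s2 ~ N(m, s2*v)
    a: float   # IG shape; posterior df = 2a
    b: float   # IG scale
    n_obs: int

    def __post_init__(self) -> None:
        if self.v <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("degenerate posterior")

    @property
    def df(self) -> float:
        return 2.0 * self.a

    @property
    def beta_mean(self) -> float:
        return self.m

    @property
    def beta_sd(self) -> float:
        """Marginal posterior sd of beta (Student-t; defined for df > 2)."""
        scale2 = self.b / self.a * self.v
        if self.df <= 2:
            return math.sqrt(scale2)
        return math.sqrt(scale2 * self.df / (self.df - 2.0))

    @property
    def sigma2_mean(self) -> float:
        if self.a <= 1:
            raise ValueError("sigma^2 posterior mean undefined for a <= 1")
        return self.b / (self.a - 1.0)


def growth_observations(history_n: AbundanceSeries,
                        history_w: StandardizedWetlandSeries) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (W_std_s, log(N_{s+1}/N_s)) pairs over consecutive years."""
    xs, ys = [], []
    for i in range(len(history_n) - 1):
        y0, y1 = int(history_n.years[i]), int(history_n.years[i + 1])
        if y1 - y0 != 1:
            continue  # never form a growth rate across a survey gap
        try:
            w = history_w.value_at(y0)
        except KeyError:
            continue
        xs.append(w)
        ys.append(math.log(history_n.n[i + 1] / history_n.n[i]))
    return np.asarray(xs), np.asarray(ys)


def fit_wetland_model(history_n: AbundanceSeries, history_w: StandardizedWetlandSeries,
                      prior: NIGPrior | None = None) -> WetlandModelPosterior:
    """Conjugate update for log growth regressed through the origin on W_std.

    Deterministic given its inputs; refitting in one batch equals any
    sequence of partial conjugate updates on the same data.
    """
    prior = prior or NIGPrior()
    x, y = growth_observations(history_n, history_w)
    if len(x) < 3:
        raise ValueError(f"wetland model needs >= 3 growth observations, got {len(x)}")
    return _conjugate_update(prior, x, y, len(x))


def _conjugate_update(prior: NIGPrior, x: np.ndarray, y: np.ndarray,
                      n_total: int) -> WetlandModelPosterior:
    sxx = float(np.dot(x, x))
    sxy = float(np.dot(x, y))
    syy = float(np.dot(y, y))
    vn = 1.0 / (1.0 / prior.v0 + sxx)
    mn = vn * (prior.m0 / prior.v0 + sxy)
    an = prior.a0 + len(x) / 2.0
    bn = prior.b0 + 0.5 * (syy + prior.m0**2 / prior.v0 - mn**2 / vn)
    return WetlandModelPosterior(m=mn, v=vn, a=an, b=max(bn, 1e-300), n_obs=n_total)


def sequential_update(post: WetlandModelPosterior, x: np.ndarray,
                      y: np.ndarray) -> WetlandModelPosterior:
    """Treat an existing posterior as the prior for a further data chunk."""
    as_prior = NIGPrior(m0=post.m, v0=post.v, a0=post.a, b0=post.b)
    return _conjugate_update(as_prior, np.asarray(x, float), np.asarray(y, float),
                             post.n_obs + len(x))


def wetland_forecast(post: WetlandModelPosterior, n_t: float, w_std_t: float,
                     year: int) -> ForecastRecord:
    """Posterior-predictive forecast: log N_{t+1} is Student-t.

    location  log N_t + beta_hat * W_std_t
    scale     sqrt(b/a * (1 + v * W_std_t^2))   (parameter uncertainty included)
    df        2a
    """
    if n_t <= 0:
        raise ValueError(f"abundance must be positive, got {n_t}")
    loc = math.log(n_t) + post.m * w_std_t
    scale = math.sqrt(post.b / post.a * (1.0 + post.v * w_std_t**2))
    mean, sd = t_log_moments(loc, scale, post.df)
    return ForecastRecord(WETLAND_ID, year + 1, mean, sd, "student-t",
                          {"loc": loc, "scale": scale, "df": post.df,
                           "beta_mean": post.m, "n_obs": post.n_obs})
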