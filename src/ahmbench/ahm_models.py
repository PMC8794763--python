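"""Mechanistic population models used in mallard adaptive harvest management.

Four candidate models arise factorially from two survival hypotheses —
additive versus (completely) compensatory harvest mortality — crossed with
two reproduction hypotheses — weak versus strong density dependence. Each
model projects spring abundance one year ahead through an age- and
sex-structured balance equation:

    N_{t+1} = gamma_S * N_t * [ m*S_am + (1-m)*( S_af
                + gamma_R * R_t * ( S_jf + S_jm * phi_ratio ) ) ]

where m is the male proportion of the breeding population, S_* are annual
survival probabilities of the four age-sex classes, R_t is the reproductive
rate (young per adult female), phi_ratio is the female:male ratio of summer
survival of juveniles, and gamma_S/gamma_R are bias-correction multipliers
(1 by default). Process noise is multiplicative lognormal, so the one-step
predictive distribution has its *median* at the deterministic projection.

Survival submodels (K = kill rate, s0 = survival absent hunting):

    additive:      S = s0 * (1 - K)
    compensatory:  S = s0            for K <= 1 - s0
                   S = 1 - K         for K >  1 - s0   (threshold C = 1 - s0)

Reproduction submodel (zero-truncated linear):

    R_t = max(0, a0 + a1 * N_t + a2 * W_std_t),   a1 <= 0, a2 >= 0

"weak" and "strong" density dependence share this form and differ in the
magnitude of a1 (and the intercept a0 that keeps both viable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .records import ForecastRecord, lognormal_record
from .series_io import HARVEST_CLASSES

__all__ = [
    "SurvivalParams",
    "ReproParams",
    "BalanceParams",
    "ClassSurvival",
    "AHMParams",
    "AHM_MODEL_IDS",
    "default_params",
    "kill_rate",
    "survival_additive",
    "survival_compensatory",
    "class_survival",
    "reproduction_rate",
    "balance_step",
    "ahm_forecast",
]

AHM_MODEL_IDS = ("SaRw", "SaRs", "ScRw", "ScRs")


@dataclass(frozen=True)
class SurvivalParams:
    """Baseline survival absent hunting per age-sex class, plus crippling loss."""

    s0: Mapping[str, float]
    c: float = 0.2

    def __post_init__(self) -> None:
        if set(self.s0) != set(HARVEST_CLASSES):
            raise ValueError(f"s0 must cover classes {HARVEST_CLASSES}")
        for cls, v in self.s0.items():
            if not 0 < v <= 1:
                raise ValueError(f"s0[{cls}] must lie in (0, 1], got {v}")
        if not 0 <= self.c < 1:
            raise ValueError(f"crippling loss must lie in [0, 1), got {self.c}")


@dataclass(frozen=True)
class ReproParams:
    a0: float  # intercept, young per adult female
    a1: float  # slope on abundance (per million birds), <= 0
    a2: float  # slope on standardized wetlands (per z-unit), >= 0

    def __post_init__(self) -> None:
        if self.a1 > 0:
            raise ValueError("density-dependence slope a1 must be <= 0")
        if self.a2 < 0:
            raise ValueError("wetland slope a2 must be >= 0")


@dataclass(frozen=True)
class BalanceParams:
    gamma_s: float = 1.0   # survival bias-correction multiplier
    gamma_r: float = 1.0   # reproduction bias-correction multiplier
    m: float = 0.55        # male proportion of the breeding population
    phi_ratio: float = 0.9  # female:male juvenile summer survival ratio
    process_sd: float = 0.05  # lognormal process noise sd (log scale)

    def __post_init__(self) -> None:
        if self.gamma_s <= 0 or self.gamma_r <= 0:
            raise ValueError("bias-correction multipliers must be positive")
        if not 0 < self.m < 1:
            raise ValueError(f"male proportion must lie in (0, 1), got {self.m}")
        if self.phi_ratio <= 0:
            raise ValueError("phi_ratio must be positive")
        if self.process_sd < 0:
            raise ValueError("process_sd must be >= 0")


@dataclass(frozen=True)
class ClassSurvival:
    s_am: float
    s_af: float
    s_jm: float
    s_jf: float

    def __post_init__(self) -> None:
        for name in ("s_am", "s_af", "s_jm", "s_jf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class AHMParams:
    """Everything the four mechanistic models need."""

    survival: SurvivalParams
    repro_weak: ReproParams
    repro_strong: ReproParams
    balance: BalanceParams = field(default_factory=BalanceParams)

    def repro(self, model_id: str) -> ReproParams:
        return self.repro_weak if model_id.endswith("Rw") else self.repro_strong


def default_params() -> AHMParams:
    """Synthetic default parameterization (illustrative, not official values).

    Weak and strong density dependence are calibrated to agree at 8 million
    birds so that both reproduction submodels are viable near the abundances
    the generator produces; see docs/methods.md for the full rationale.
    """
    return AHMParams(
        survival=SurvivalParams(s0={"am": 0.85, "af": 0.75, "jm": 0.80, "jf": 0.70}, c=0.2),
        repro_weak=ReproParams(a0=1.1, a1=-0.05, a2=0.2),
        repro_strong=ReproParams(a0=1.9, a1=-0.15, a2=0.2),
        balance=BalanceParams(),
    )


def kill_rate(h: float, c: float) -> float:
    """Kill rate K = h / (1 - c): harvest rate inflated for crippling loss."""
    if not 0 <= h < 1:
        raise ValueError(f"harvest rate must lie in [0, 1), got {h}")
    if not 0 <= c < 1:
        raise ValueError(f"crippling loss must lie in [0, 1), got {c}")
    k = h / (1.0 - c)
    if k >= 1:
        raise ValueError(f"kill rate {k:.4f} >= 1: total kill exceeds population")
    return k


def survival_additive(s0: float, k: float) -> float:
    """Additive harvest mortality: S = s0 * (1 - K)."""
    if not 0 <= k < 1:
        raise ValueError(f"kill rate must lie in [0, 1), got {k}")
    return s0 * (1.0 - k)


def survival_compensatory(s0: float, k: float) -> float:
    """Completely compensatory mortality below the threshold C = 1 - s0.

    Harvest up to C is absorbed by reduced natural mortality (S = s0);
    beyond it every extra kill is additive (S = 1 - K). Continuous at C.
    """
    if not 0 <= k < 1:
        raise ValueError(f"kill rate must lie in [0, 1), got {k}")
    c_thresh = 1.0 - s0
    return s0 if k <= c_thresh else 1.0 - k


def class_survival(p: SurvivalParams, harvest: Mapping[str, float], form: str) -> ClassSurvival:
    """Per-class annual survival under the given harvest rates and hypothesis."""
    if form not in ("additive", "compensatory"):
        raise ValueError(f"unknown survival form {form!r}")
    fn = survival_additive if form == "additive" else survival_compensatory
    s = {cls: fn(p.s0[cls], kill_rate(harvest[cls], p.c)) for cls in HARVEST_CLASSES}
    return ClassSurvival(s_am=s["am"], s_af=s["af"], s_jm=s["jm"], s_jf=s["jf"])


def reproduction_rate(p: ReproParams, n_t: float, w_std: float) -> float:
    """Zero-truncated linear reproductive rate R_t (young per adult female)."""
    if n_t <= 0:
        raise ValueError(f"abundance must be positive, got {n_t}")
    return max(0.0, p.a0 + p.a1 * n_t + p.a2 * w_std)


def balance_step(bp: BalanceParams, n_t: float, s: ClassSurvival, r_t: float) -> float:
    """Deterministic one-year projection through the balance equation."""
    if n_t <= 0:
        raise ValueError(f"abundance must be positive, got {n_t}")
    if r_t < 0:
        raise ValueError(f"reproductive rate must be >= 0, got {r_t}")
    recruits = bp.gamma_r * r_t * (s.s_jf + s.s_jm * bp.phi_ratio)
    n_next = bp.gamma_s * n_t * (bp.m * s.s_am + (1.0 - bp.m) * (s.s_af + recruits))
    if n_next <= 0:
        raise ValueError("balance equation produced nonpositive abundance; parameterization inconsistent")
    return n_next


def ahm_forecast(model_id: str, year: int, n_t: float, w_std_t: float,
                 harvest_t: Mapping[str, float], params: AHMParams,
                 obs_se: float | None = None) -> ForecastRecord:
    """One-step-ahead predictive distribution for one mechanistic model.

    The prediction is lognormal with median at the balance-equation output
    and log-scale sd ``process_sd``; a supplied survey SE (millions) is
    converted to the log scale by the delta method and added on the variance
    scale.
    """
    if model_id not in AHM_MODEL_IDS:
        raise ValueError(f"unknown AHM model id {model_id!r}; expected one of {AHM_MODEL_IDS}")
    form = "additive" if model_id.startswith("Sa") else "compensatory"
    s = class_survival(params.survival, harvest_t, form)
    r_t = reproduction_rate(params.repro(model_id), n_t, w_std_t)
    median = balance_step(params.balance, n_t, s, r_t)
    var_log = params.balance.process_sd**2
    if obs_se is not None and obs_se > 0:
        var_log += (obs_se / median) ** 2
    return lognormal_record(model_id, year + 1, median, math.sqrt(var_log))


def with_process_sd(params: AHMParams, process_sd: float) -> AHMParams:
    return replace(params, balance=replace(params.balance, process_sd=process_sd))
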