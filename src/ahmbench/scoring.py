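"""Point-forecast skill scores and null-model benchmark ratios.

Errors are defined as predicted - observed, so a model that systematically
*under*predicts has a negative mean signed difference. Both normalized
scores divide by the mean observed abundance over the scored years, making
them unitless and comparable across models and rescalings:

    RMSE  = sqrt(mean((pred - obs)^2))        NRMSE = RMSE / mean(obs)
    MSD   = mean(pred - obs)                  NMSD  = MSD / mean(obs)

NRMSE blends bias with precision; NMSD isolates systematic bias, the
tell-tale signature of a misspecified model. "k times better" than a null
is operationalized as the ratio of absolute NMSDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["SkillScores", "SkillReport", "rmse", "nrmse", "msd", "nmsd", "skill_report"]

SCORE_VERSION = "nrmse-nmsd-1"


def _align(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) < 1:
        raise ValueError(f"pred/obs must be equal-length 1-d arrays, got {p.shape} vs {o.shape}")
    return p, o


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    p, o = _align(pred, obs)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def msd(pred: Sequence[float], obs: Sequence[float]) -> float:
    p, o = _align(pred, obs)
    return float(np.mean(p - o))


def _obs_mean(obs: np.ndarray) -> float:
    m = float(np.mean(obs))
    if m <= 0:
        raise ValueError(f"mean observed abundance must be positive, got {m}")
    return m


def nrmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    p, o = _align(pred, obs)
    return rmse(p, o) / _obs_mean(o)


def nmsd(pred: Sequence[float], obs: Sequence[float]) -> float:
    p, o = _align(pred, obs)
    return msd(p, o) / _obs_mean(o)


@dataclass(frozen=True)
class SkillScores:
    model_id: str
    rmse: float
    nrmse: float
    msd: float
    nmsd: float
    n_years: int

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("scores need >= 1 year")
        # Jensen: root-mean-square error always dominates the mean error
        if self.rmse < abs(self.msd) - 1e-12:
            raise ValueError("inconsistent scores: rmse < |msd|")


@dataclass(frozen=True)
class SkillReport:
    """Per-model scores over common years plus benchmark ratios vs a null."""

    scores: Mapping[str, SkillScores]
    null_id: str
    nrmse_ratio: Mapping[str, float]
    abs_nmsd_ratio: Mapping[str, float]
    fails_null_benchmark: Mapping[str, bool]
    years: tuple[int, ...]
    version: str = SCORE_VERSION

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "null_id": self.null_id,
            "n_years": len(self.years),
            "years": list(self.years),
            "models": {
                m: {
                    "rmse": s.rmse, "nrmse": s.nrmse, "msd": s.msd, "nmsd": s.nmsd,
                    "n_years": s.n_years,
                    "nrmse_ratio_vs_null": self.nrmse_ratio[m],
                    "abs_nmsd_ratio_vs_null": self.abs_nmsd_ratio[m],
                    "fails_null_benchmark": self.fails_null_benchmark[m],
                }
                for m, s in self.scores.items()
            },
        }


def skill_report(table, null_id: str, models: Sequence[str] | None = None) -> SkillReport:
    """Score every model over the common scored years and benchmark vs the null.

    ``table`` is a :class:`~ahmbench.harness.ForecastTable`. Scores use only
    years where *every* compared model has a forecast and an observation
    exists, so the ratios are computed on identical data. A null NMSD of 0
    makes the NMSD ratios infinite (flagged), not an error.
    """
    ids = list(models) if models is not None else list(table.models())
    if null_id not in ids:
        raise ValueError(f"null model {null_id!r} not among scored models {ids}")
    years = table.common_years(ids)
    if not years:
        raise ValueError("no common scored years")
    obs = np.array([table.observed[y] for y in years])

    scores: dict[str, SkillScores] = {}
    for m in ids:
        pred = np.array([table.get(m, y).mean for y in years])
        scores[m] = SkillScores(m, rmse(pred, obs), nrmse(pred, obs),
                                msd(pred, obs), nmsd(pred, obs), len(years))

    null = scores[null_id]
    nrmse_ratio, nmsd_ratio, fails = {}, {}, {}
    for m in ids:
        nrmse_ratio[m] = scores[m].nrmse / null.nrmse if null.nrmse > 0 else (
            1.0 if scores[m].nrmse == 0 else math.inf)
        nmsd_ratio[m] = abs(scores[m].nmsd) / abs(null.nmsd) if null.nmsd != 0 else (
            1.0 if scores[m].nmsd == 0 else math.inf)
        fails[m] = nmsd_ratio[m] > 1.0
    return SkillReport(scores, null_id, nrmse_ratio, nmsd_ratio, fails, tuple(years))
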