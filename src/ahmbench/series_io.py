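"""Domain time-series containers, CSV I/O, wetland standardization, run config.

All series are annual, keyed by calendar year, on the reporting scale of the
continental waterfowl survey: abundance and ponds in millions. Years must be
strictly increasing; gaps (missed survey years) are permitted and are handled
downstream by never forecasting or scoring across them.

CSV layouts
-----------
abundance : ``year,n_millions[,se_millions]``
wetland   : ``year,ponds_millions``
harvest   : ``year,k_am,k_af,k_jm,k_jf``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AbundanceSeries",
    "WetlandSeries",
    "StandardizedWetlandSeries",
    "HarvestSeries",
    "RunConfig",
    "read_series",
    "write_series",
    "standardize_wetlands",
]

HARVEST_CLASSES = ("am", "af", "jm", "jf")


def _check_years(years: np.ndarray) -> None:
    if len(years) == 0:
        raise ValueError("series has no rows")
    dup = pd.Series(years)[pd.Series(years).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate year(s) in series: {sorted(set(int(y) for y in dup))}")
    if not np.all(np.diff(years) > 0):
        raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class AbundanceSeries:
    """Observed breeding-population abundance N_t (millions), optional survey SE."""

    years: np.ndarray
    n: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        _check_years(self.years)
        if len(self.n) != len(self.years):
            raise ValueError("N and years differ in length")
        if np.any(self.n <= 0):
            bad = self.years[self.n <= 0]
            raise ValueError(f"nonpositive abundance at year(s) {bad.tolist()}")
        if self.se is not None:
            object.__setattr__(self, "se", np.asarray(self.se, dtype=float))
            if len(self.se) != len(self.years):
                raise ValueError("se and years differ in length")
            if np.any(self.se < 0):
                raise ValueError("survey SE must be nonnegative")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.years) > 1))

    def value_at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"no observation for year {year}")
        return float(self.n[idx[0]])

    def se_at(self, year: int) -> float | None:
        if self.se is None:
            return None
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"no observation for year {year}")
        return float(self.se[idx[0]])

    def truncate(self, last_year: int) -> "AbundanceSeries":
        """History through ``last_year`` inclusive (no look-ahead)."""
        keep = self.years <= last_year
        if not keep.any():
            raise ValueError(f"no data at or before year {last_year}")
        se = self.se[keep] if self.se is not None else None
        return AbundanceSeries(self.years[keep], self.n[keep], se)

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, "n_millions": self.n}
        if self.se is not None:
            data["se_millions"] = self.se
        return pd.DataFrame(data)


@dataclass(frozen=True)
class WetlandSeries:
    """May pond counts W_t (millions of ponds)."""

    years: np.ndarray
    w_raw: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "w_raw", np.asarray(self.w_raw, dtype=float))
        _check_years(self.years)
        if len(self.w_raw) != len(self.years):
            raise ValueError("W and years differ in length")
        if np.any(self.w_raw <= 0):
            raise ValueError("pond counts must be positive")

    def __len__(self) -> int:
        return len(self.years)

    def truncate(self, last_year: int) -> "WetlandSeries":
        keep = self.years <= last_year
        if not keep.any():
            raise ValueError(f"no wetland data at or before year {last_year}")
        return WetlandSeries(self.years[keep], self.w_raw[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "ponds_millions": self.w_raw})


@dataclass(frozen=True)
class StandardizedWetlandSeries:
    """Unitless wetland z-scores with the standardization constants recorded.

    ``baseline_mean``/``baseline_sd`` are scalars in fixed-baseline mode and
    per-year arrays in recursive (expanding-window) mode, where year t's
    z-score uses only data through year t.
    """

    years: np.ndarray
    w_std: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    mode: str = "fixed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "w_std", np.asarray(self.w_std, dtype=float))
        object.__setattr__(self, "baseline_mean", np.atleast_1d(np.asarray(self.baseline_mean, dtype=float)))
        object.__setattr__(self, "baseline_sd", np.atleast_1d(np.asarray(self.baseline_sd, dtype=float)))
        _check_years(self.years)
        if np.any(self.baseline_sd <= 0):
            raise ValueError("baseline sd must be positive")

    def value_at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"no standardized wetland value for year {year}")
        return float(self.w_std[idx[0]])

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class HarvestSeries:
    """Per-class harvest rates in [0,1) for {adult, juvenile} x {male, female}."""

    years: np.ndarray
    k: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        _check_years(self.years)
        if set(self.k) != set(HARVEST_CLASSES):
            raise ValueError(f"harvest classes must be {HARVEST_CLASSES}, got {sorted(self.k)}")
        k = {c: np.asarray(v, dtype=float) for c, v in self.k.items()}
        object.__setattr__(self, "k", k)
        for c, v in k.items():
            if len(v) != len(self.years):
                raise ValueError(f"harvest class {c} length mismatch")
            if np.any((v < 0) | (v >= 1)):
                raise ValueError(f"harvest rates for class {c} must lie in [0, 1)")

    def __len__(self) -> int:
        return len(self.years)

    def rates_at(self, year: int) -> dict[str, float]:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"no harvest rates for year {year}")
        return {c: float(self.k[c][idx[0]]) for c in HARVEST_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years}
        for c in HARVEST_CLASSES:
            data[f"k_{c}"] = self.k[c]
        return pd.DataFrame(data)


def read_series(path: str | Path, kind: str):
    """Read a validated series from CSV; rows are sorted by year first.

    ``kind`` is one of ``{"abundance", "wetland", "harvest"}``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "year" not in df.columns:
        raise ValueError(f"{path}: missing 'year' column")
    df = df.sort_values("year").reset_index(drop=True)
    years = df["year"].to_numpy()
    dup = df["year"][df["year"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate year(s) {sorted(set(int(y) for y in dup))}")
    if kind == "abundance":
        se = df["se_millions"].to_numpy() if "se_millions" in df.columns else None
        return AbundanceSeries(years, df["n_millions"].to_numpy(), se)
    if kind == "wetland":
        return WetlandSeries(years, df["ponds_millions"].to_numpy())
    if kind == "harvest":
        k = {c: df[f"k_{c}"].to_numpy() for c in HARVEST_CLASSES}
        return HarvestSeries(years, k)
    raise ValueError(f"unknown series kind {kind!r}")


def write_series(series, path: str | Path) -> None:
    series.to_frame().to_csv(Path(path), index=False)


def standardize_wetlands(w: WetlandSeries, baseline="recursive") -> StandardizedWetlandSeries:
    """Standardize pond counts to z-scores (sample sd, n-1 denominator).

    ``baseline`` may be ``"recursive"`` (expanding window: year t uses data
    through year t only, so the series starts at the second observed year),
    ``"full"`` (whole series), or a ``(first_year, last_year)`` window.
    """
    if isinstance(baseline, str) and baseline == "recursive":
        if len(w) < 2:
            raise ValueError("recursive standardization needs >= 2 years")
        years, z, means, sds = [], [], [], []
        for i in range(1, len(w)):
            hist = w.w_raw[: i + 1]
            m = float(np.mean(hist))
            s = float(np.std(hist, ddof=1))
            if s == 0:
                raise ValueError(f"degenerate standardization: zero sd through year {int(w.years[i])}")
            years.append(int(w.years[i]))
            z.append((w.w_raw[i] - m) / s)
            means.append(m)
            sds.append(s)
        return StandardizedWetlandSeries(np.array(years), np.array(z), np.array(means), np.array(sds), mode="recursive")

    if isinstance(baseline, str) and baseline == "full":
        window = (int(w.years[0]), int(w.years[-1]))
    else:
        window = (int(baseline[0]), int(baseline[1]))
    mask = (w.years >= window[0]) & (w.years <= window[1])
    if mask.sum() < 2:
        raise ValueError("baseline window must contain >= 2 years")
    m = float(np.mean(w.w_raw[mask]))
    s = float(np.std(w.w_raw[mask], ddof=1))
    if s == 0:
        raise ValueError("degenerate standardization: zero sd over baseline window")
    return StandardizedWetlandSeries(w.years, (w.w_raw - m) / s, m, s, mode="fixed")


@dataclass
class RunConfig:
    """Run configuration mirroring the YAML config file.

    Either the three ``data`` paths or a ``scenario`` block (forwarded to the
    synthetic-data generator) must be present.
    """

    models: Sequence[str] = ("SaRw", "SaRs", "ScRw", "ScRs", "persistence", "wetland")
    eval_start: int = 1996
    eval_end: int = 2019
    seed: int = 0
    standardization: str = "recursive"
    weighted_models: Sequence[str] = ("SaRw", "SaRs", "ScRw", "ScRs")
    null_id: str = "persistence"
    data: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    ahm: dict = field(default_factory=dict)
    null_models: dict = field(default_factory=dict)
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.eval_end < self.eval_start:
            raise ValueError("eval_end must be >= eval_start")
        if not self.models:
            raise ValueError("at least one model must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "eval_start": self.eval_start,
            "eval_end": self.eval_end,
            "seed": self.seed,
            "standardization": self.standardization,
            "weighted_models": list(self.weighted_models),
            "null_id": self.null_id,
            "data": dict(self.data),
            "scenario": dict(self.scenario),
            "ahm": dict(self.ahm),
            "null_models": dict(self.null_models),
            "outdir": self.outdir,
        }
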