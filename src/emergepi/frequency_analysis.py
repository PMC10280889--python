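"""Per-year diagnosis frequency tables, per-100k normalization, ranking and
95% prediction intervals.

The central object is the ranked profile: diagnosis categories ordered by
their across-year mean frequency (the "sorted histogram" of emergency
epidemiology), each carrying a t-based 95% prediction interval for a single
future year's frequency computed from the annual replicates.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .icd_processing import AdmissionRecord, chapter_of
from .synthetic_data import ConfigurationError

__all__ = [
    "UndefinedIntervalError",
    "YearlyFrequencyTable",
    "ProfileEntry",
    "RankedProfile",
    "RankStability",
    "tabulate",
    "normalize_per_100k",
    "prediction_interval",
    "rank_by_mean",
    "rank_stability",
]

Scale = Literal["per_100k", "count"]


class UndefinedIntervalError(ValueError):
    """Prediction interval requested from fewer than two annual replicates."""


@dataclass(frozen=True)
class YearlyFrequencyTable:
    """Category x year admission counts plus per-year catchment populations.

    ``counts`` has one row per diagnosis category, one integer column per
    year; absent combinations are zero. ``scope`` records which subset of the
    stream was tabulated (``"all"``, ``"chapter:G"``, ``"roster:medical"``, ...).
    """

    counts: pd.DataFrame
    population_per_year: Mapping[int, float]
    scope: str = "all"

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.counts.columns]

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path: str | Path) -> None:
        self.counts.rename_axis("category").to_csv(path)


def tabulate(
    records: Iterable[AdmissionRecord],
    populations: Mapping[int, float],
    scope: str = "all",
) -> YearlyFrequencyTable:
    """Count admissions per (category, year) within a scope.

    Records must already be preprocessed (3-character categories, Z-chapter
    excluded). ``scope`` is ``"all"``, ``"chapter:<group>"`` (capital-letter
    chapter group, e.g. ``"chapter:A/B"``) or ``"roster:<label>"`` (requires
    roster-classified records). A record whose year has no population entry
    is a configuration error.
    """
    if scope == "all":
        keep = lambda r: True  # noqa: E731
    elif scope.startswith("chapter:"):
        group = scope.split(":", 1)[1]
        keep = lambda r: chapter_of(r.icd10_code) == group  # noqa: E731
    elif scope.startswith("roster:"):
        label = scope.split(":", 1)[1]
        keep = lambda r: r.roster == label  # noqa: E731
    else:
        raise ConfigurationError("scope", f"unrecognized scope {scope!r}")

    cats, years = [], []
    for rec in records:
        if rec.year not in populations:
            raise ConfigurationError(
                "populations", f"no catchment population for year {rec.year}"
            )
        if keep(rec):
            cats.append(rec.icd10_code)
            years.append(rec.year)

    if cats:
        counts = pd.crosstab(pd.Index(cats, name="category"), pd.Index(years, name="year"))
    else:
        counts = pd.DataFrame(dtype=int)
    # every configured year appears as a column, even if empty in this scope
    for y in sorted(populations):
        if y not in counts.columns:
            counts[y] = 0
    counts = counts[sorted(counts.columns)].astype(int).sort_index()
    return YearlyFrequencyTable(counts=counts, population_per_year=dict(populations), scope=scope)


def normalize_per_100k(count: float, population: float) -> float:
    """Admissions per 100,000 catchment inhabitants: ``count * 1e5 / population``."""
    if population <= 0:
        raise ConfigurationError("population", "must be > 0")
    return count * 100_000.0 / population


def prediction_interval(
    values: Sequence[float], level: float = 0.95, clip_at_zero: bool = True
) -> tuple[float, float]:
    """Two-sided t prediction interval for one future annual observation.

    For n observed years with sample mean m and sample standard deviation s,
    the interval is ``m ± t(1-(1-level)/2, n-1) * s * sqrt(1 + 1/n)``. The
    lower bound is clipped at 0 by default since frequencies are
    non-negative. Requires at least two values.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise UndefinedIntervalError("prediction interval needs >= 2 annual values")
    m = x.mean()
    s = x.std(ddof=1)
    half = stats.t.ppf(1 - (1 - level) / 2, n - 1) * s * math.sqrt(1 + 1 / n)
    lo, hi = m - half, m + half
    if clip_at_zero:
        lo = max(lo, 0.0)
    return float(lo), float(hi)


@dataclass(frozen=True)
class ProfileEntry:
    category: str
    chapter_group: str
    mean: float  # on the profile's scale (per-100k by default)
    pi_lower: float
    pi_upper: float
    mean_count: float  # across-year mean raw count, always kept


@dataclass(frozen=True)
class RankedProfile:
    """Categories ordered by across-year mean frequency, with 95% PIs.

    ``coverage_truncation`` < 1 drops the long tail: only the smallest prefix
    of ranks whose cumulative share reaches that fraction is kept.
    """

    entries: tuple[ProfileEntry, ...]
    n_years: int
    scale: Scale = "per_100k"
    coverage_truncation: float = 1.0
    pi_level: float = 0.95
    scope: str = "all"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.entries) + 1)

    @property
    def frequencies(self) -> np.ndarray:
        """Mean frequencies on the profile's scale, in rank order."""
        return np.array([e.mean for e in self.entries])

    @property
    def mean_counts(self) -> np.ndarray:
        return np.array([e.mean_count for e in self.entries])

    def to_dataframe(self) -> pd.DataFrame:
        scale_factor = (
            1.0
            if self.scale == "per_100k"
            else np.nan  # per-100k column is only meaningful on that scale
        )
        rows = []
        for rank, e in enumerate(self.entries, start=1):
            rows.append(
                {
                    "category": e.category,
                    "chapter_group": e.chapter_group,
                    "rank": rank,
                    "mean_per_100k": e.mean * scale_factor,
                    "pi_lower": e.pi_lower,
                    "pi_upper": e.pi_upper,
                    "mean_count": e.mean_count,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scale": self.scale,
            "n_years": self.n_years,
            "coverage_truncation": self.coverage_truncation,
            "pi_level": self.pi_level,
            "scope": self.scope,
            "rank_index": "1-based",
            "entries": self.to_dataframe().to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def rank_by_mean(
    table: YearlyFrequencyTable,
    coverage_truncation: float = 1.0,
    scale: Scale = "per_100k",
    pi_level: float = 0.95,
    truncation_basis: Literal["admissions", "categories"] = "admissions",
) -> RankedProfile:
    """Rank categories by across-year mean frequency and attach 95% PIs.

    The ranking key is one global order — the across-year mean on the chosen
    scale — with exact ties broken lexicographically by category code. The
    prediction interval is computed on the same scale that is displayed.
    With a single observed year the interval degenerates to zero width at
    the mean.

    ``coverage_truncation`` keeps the minimal top-rank prefix whose
    cumulative share of mean admissions (basis ``"admissions"``) or of the
    number of categories (basis ``"categories"``) reaches the given fraction.
    """
    if not 0 < coverage_truncation <= 1:
        raise ConfigurationError("coverage_truncation", "must lie in (0, 1]")
    if table.counts.empty:
        raise ConfigurationError("table", f"no admissions in scope {table.scope!r}")

    counts = table.counts
    years = table.years
    pops = np.array([table.population_per_year[y] for y in years], dtype=float)
    raw = counts.to_numpy(dtype=float)
    values = raw * 100_000.0 / pops if scale == "per_100k" else raw

    means = values.mean(axis=1)
    mean_counts = raw.mean(axis=1)
    order = sorted(
        range(len(means)), key=lambda i: (-means[i], counts.index[i])
    )

    entries = []
    for i in order:
        if len(years) >= 2:
            lo, hi = prediction_interval(values[i], level=pi_level)
        else:
            lo = hi = float(means[i])
        entries.append(
            ProfileEntry(
                category=str(counts.index[i]),
                chapter_group=chapter_of(str(counts.index[i])),
                mean=float(means[i]),
                pi_lower=lo,
                pi_upper=hi,
                mean_count=float(mean_counts[i]),
            )
        )

    if coverage_truncation < 1.0:
        if truncation_basis == "admissions":
            shares = np.cumsum([e.mean_count for e in entries])
            shares = shares / shares[-1]
            n_keep = int(np.searchsorted(shares, coverage_truncation - 1e-12) + 1)
        else:
            n_keep = math.ceil(coverage_truncation * len(entries))
        entries = entries[:n_keep]

    return RankedProfile(
        entries=tuple(entries),
        n_years=len(years),
        scale=scale,
        coverage_truncation=coverage_truncation,
        pi_level=pi_level,
        scope=table.scope,
    )


@dataclass(frozen=True)
class RankStability:
    """Spearman rank correlations between every pair of yearly orderings."""

    pairwise: dict[tuple[int, int], float]
    minimum: float
    mean: float


def rank_stability(table: YearlyFrequencyTable) -> RankStability:
    """How reproducible the diagnosis ordering is from year to year.

    Computes the Spearman rank correlation of per-category counts between
    every pair of years; a stable emergency epidemiology shows correlations
    near 1 for all pairs.
    """
    years = table.years
    if len(years) < 2:
        raise ConfigurationError("table", "rank stability needs >= 2 years")
    pairwise: dict[tuple[int, int], float] = {}
    for y1, y2 in itertools.combinations(years, 2):
        a, b = table.counts[y1].to_numpy(), table.counts[y2].to_numpy()
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            # a fully tied year has no rank order to correlate
            pairwise[(y1, y2)] = float("nan")
            continue
        rho = stats.spearmanr(a, b).statistic
        pairwise[(y1, y2)] = float(rho)
    vals = np.array(list(pairwise.values()))
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        minimum = mean = float("nan")
    else:
        minimum, mean = float(finite.min()), float(finite.mean())
    return RankStability(pairwise=pairwise, minimum=minimum, mean=mean)
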