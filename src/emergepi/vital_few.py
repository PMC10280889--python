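"""Cumulative coverage curves and "vital few" duty-roster competence lists.

The vital few are the minimal set of most frequent diagnoses covering a
target share (conventionally 80%) of admissions; a chapter or roster scope
satisfies the classic community-diagnosis criterion when its ten most
frequent categories already cover at least 80% of its case load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .frequency_analysis import RankedProfile

__all__ = [
    "CumulativeEntry",
    "CumulativeProfile",
    "VitalFewReport",
    "cumulative_curve",
    "vital_few_set",
    "top_k_share",
]


class EmptyScopeError(ValueError):
    """Cumulative analysis requested on a scope with zero admissions."""


@dataclass(frozen=True)
class CumulativeEntry:
    rank: int
    category: str
    chapter_group: str
    count: float
    share: float  # this category's share of the scope total
    cumulative_share: float


@dataclass(frozen=True)
class CumulativeProfile:
    """Running share of total admissions covered by the top-r categories."""

    entries: tuple[CumulativeEntry, ...]
    total: float
    scope: str = "all"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def cumulative_shares(self) -> np.ndarray:
        return np.array([e.cumulative_share for e in self.entries])


@dataclass(frozen=True)
class VitalFewReport:
    """The minimal top-rank prefix covering a target share of admissions."""

    threshold: float
    categories: tuple[str, ...]
    coverage: float  # share actually covered by the prefix
    top10_share: float
    pareto_principle_met: bool  # ten most frequent cover >= 80%
    scope: str = "all"


def cumulative_curve(profile: RankedProfile) -> CumulativeProfile:
    """Cumulative admission shares along the ranked profile.

    Shares are computed from mean raw counts (shares of admissions, not of
    normalized rates — the two coincide when populations are constant). The
    curve is monotone and ends at 1.
    """
    counts = profile.mean_counts
    total = float(counts.sum())
    if len(profile) == 0 or total <= 0:
        raise EmptyScopeError(f"no admissions in scope {profile.scope!r}")
    cum = np.cumsum(counts) / total
    entries = tuple(
        CumulativeEntry(
            rank=r,
            category=e.category,
            chapter_group=e.chapter_group,
            count=float(counts[r - 1]),
            share=float(counts[r - 1] / total),
            cumulative_share=float(cum[r - 1]),
        )
        for r, e in enumerate(profile.entries, start=1)
    )
    return CumulativeProfile(entries=entries, total=total, scope=profile.scope)


def top_k_share(curve: CumulativeProfile, k: int = 10) -> float:
    """Share of admissions covered by the k most frequent categories (exact)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(curve.entries[min(k, len(curve)) - 1].cumulative_share)


def vital_few_set(curve: CumulativeProfile, threshold: float = 0.8) -> VitalFewReport:
    """Minimal top-rank prefix whose cumulative share reaches the threshold.

    Attainment uses >= ("making up 80% of admissions"): the category whose
    inclusion first reaches the threshold is part of the vital few. The
    report also carries the top-10 share and whether it meets the 80%
    community-diagnosis criterion.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    shares = curve.cumulative_shares
    idx = int(np.searchsorted(shares, threshold - 1e-12))
    idx = min(idx, len(curve) - 1)
    prefix = curve.entries[: idx + 1]
    t10 = top_k_share(curve, 10)
    return VitalFewReport(
        threshold=threshold,
        categories=tuple(e.category for e in prefix),
        coverage=float(prefix[-1].cumulative_share),
        top10_share=t10,
        pareto_principle_met=bool(t10 >= 0.8),
        scope=curve.scope,
    )


def write_vital_few_csv(
    curve: CumulativeProfile,
    report: VitalFewReport,
    path: str | Path,
    roster_of: dict[str, str] | None = None,
) -> None:
    """Competence-list CSV: rank, category, group, roster, share, cumulative share."""
    rows = []
    vital = set(report.categories)
    for e in curve.entries:
        rows.append(
            {
                "rank": e.rank,
                "category": e.category,
                "chapter_group": e.chapter_group,
                "roster": (roster_of or {}).get(e.category, ""),
                "share": e.share,
                "cumulative_share": e.cumulative_share,
                "vital_few": e.category in vital,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vital_few_json(report: VitalFewReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "scope": report.scope,
                "threshold": report.threshold,
                "n_vital_few": len(report.categories),
                "categories": list(report.categories),
                "coverage": report.coverage,
                "top10_share": report.top10_share,
                "pareto_principle_met": report.pareto_principle_met,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
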