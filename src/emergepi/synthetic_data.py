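"""Synthetic multi-year emergency-admission streams with a known rank-frequency law.

The generator emulates a hospital registry extract: one record per admission
carrying a synthetic patient id, an ICD-10-shaped diagnosis code and a
calendar year. Per-category annual counts follow a chosen ground-truth law —
exponential decay in rank, ``b0 * exp(-b1 * rank)``, or a Pareto rank-size
profile derived from the power-law density ``C * alpha * k^alpha / x^(alpha+1)``
— optionally perturbed by Poisson sampling noise, plus a configurable
fraction of Z-chapter (non-emergency) contamination to exercise the
exclusion filter downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .icd_processing import AdmissionRecord

__all__ = [
    "ConfigurationError",
    "GroundTruthLaw",
    "SimulationConfig",
    "expected_counts",
    "pareto_rank_frequencies",
    "synthetic_category_labels",
    "generate_admissions",
    "write_simulation",
]


class ConfigurationError(ValueError):
    """An invalid simulation parameter; the message names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


# Letters usable for synthetic diagnosis categories; Z is reserved for the
# contamination stream so the exclusion filter has something to exclude.
_NON_Z_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXY"

# Fixed pool of realistic Z-chapter codes for the contaminating stream.
_Z_CODES = ("Z03", "Z09", "Z38", "Z51", "Z76")


@dataclass(frozen=True)
class GroundTruthLaw:
    """Ground-truth rank-frequency law for the simulated diagnosis mix.

    Parameters
    ----------
    family:
        ``"exponential"`` — expected annual count of the rank-``r`` category
        is ``b0 * exp(-b1 * r)`` (1-based rank). ``"pareto"`` — expected
        counts follow the Pareto rank-size profile (see
        :func:`pareto_rank_frequencies`).
    b0, b1:
        Amplitude (admissions/year at decay 0) and decay rate per rank;
        exponential family only. ``b1 = 0`` gives a flat profile.
    alpha, k:
        Tail exponent and minimum frequency scale (admissions/year);
        Pareto family only.
    n_categories:
        Number of distinct non-Z diagnosis categories (>= 2).
    """

    family: Literal["exponential", "pareto"]
    n_categories: int
    b0: float | None = None
    b1: float | None = None
    alpha: float | None = None
    k: float | None = None

    def __post_init__(self):
        if self.family not in ("exponential", "pareto"):
            raise ConfigurationError("family", f"unknown family {self.family!r}")
        if self.n_categories < 2:
            raise ConfigurationError("n_categories", "must be >= 2")
        if self.n_categories > len(_NON_Z_LETTERS) * 100:
            raise ConfigurationError(
                "n_categories", f"label scheme supports at most {len(_NON_Z_LETTERS) * 100}"
            )
        if self.family == "exponential":
            if self.b0 is None or self.b0 <= 0:
                raise ConfigurationError("b0", "must be > 0 for the exponential family")
            if self.b1 is None or self.b1 < 0:
                raise ConfigurationError("b1", "must be >= 0 for the exponential family")
        else:
            if self.alpha is None or self.alpha <= 0:
                raise ConfigurationError("alpha", "must be > 0 for the pareto family")
            if self.k is None or self.k <= 0:
                raise ConfigurationError("k", "must be > 0 for the pareto family")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to synthesize one multi-year admission stream.

    ``year_factors`` is an optional multiplicative per-year trend factor
    (default 1.0 per year), emulating a general drift in admission volume
    without changing the rank order.
    """

    law: GroundTruthLaw
    years: Sequence[int]
    population_per_year: Mapping[int, float]
    z_fraction: float = 0.0
    noise: Literal["none", "poisson"] = "none"
    seed: int = 0
    year_factors: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        years = list(self.years)
        if not years:
            raise ConfigurationError("years", "must be non-empty")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigurationError("years", "must be strictly increasing")
        missing = [y for y in years if y not in self.population_per_year]
        if missing:
            raise ConfigurationError("population_per_year", f"missing years {missing}")
        if any(p <= 0 for p in self.population_per_year.values()):
            raise ConfigurationError("population_per_year", "populations must be > 0")
        if not 0 <= self.z_fraction < 1:
            raise ConfigurationError("z_fraction", "must lie in [0, 1)")
        if self.noise not in ("none", "poisson"):
            raise ConfigurationError("noise", f"unknown noise model {self.noise!r}")

    def to_dict(self) -> dict:
        law = {k: v for k, v in vars(self.law).items() if v is not None}
        return {
            "law": law,
            "years": list(self.years),
            "population_per_year": {int(y): p for y, p in self.population_per_year.items()},
            "z_fraction": self.z_fraction,
            "noise": self.noise,
            "seed": self.seed,
            "year_factors": {int(y): f for y, f in self.year_factors.items()},
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        law = GroundTruthLaw(**raw["law"])
        return cls(
            law=law,
            years=[int(y) for y in raw["years"]],
            population_per_year={int(y): float(p) for y, p in raw["population_per_year"].items()},
            z_fraction=float(raw.get("z_fraction", 0.0)),
            noise=raw.get("noise", "none"),
            seed=int(raw.get("seed", 0)),
            year_factors={int(y): float(f) for y, f in (raw.get("year_factors") or {}).items()},
        )


def pareto_rank_frequencies(alpha: float, k: float, n: int) -> np.ndarray:
    """Pareto rank-size profile: frequency at 1-based rank r is ``k * (n/r)^(1/alpha)``.

    This is the quantile mapping of the Pareto(alpha, k) law onto n ranked
    observations (rank r sits at the upper ``r/n`` tail). The smallest value
    (rank n) equals k exactly, so the downstream estimate k_hat = min(x_i)
    recovers the true scale, and at alpha = 1 the classic Zipf ``x ∝ 1/rank``
    profile is obtained.
    """
    if alpha <= 0:
        raise ConfigurationError("alpha", "must be > 0")
    if k <= 0:
        raise ConfigurationError("k", "must be > 0")
    ranks = np.arange(1, n + 1, dtype=float)
    return k * (n / ranks) ** (1.0 / alpha)


def expected_counts(law: GroundTruthLaw) -> np.ndarray:
    """Expected annual admission count per rank (1-based), strictly decreasing.

    Exponential family: ``b0 * exp(-b1 * r)``. Pareto family: the rank-size
    frequencies of :func:`pareto_rank_frequencies` taken directly as expected
    counts (k is in admissions/year).
    """
    n = law.n_categories
    if law.family == "exponential":
        ranks = np.arange(1, n + 1, dtype=float)
        return law.b0 * np.exp(-law.b1 * ranks)
    return pareto_rank_frequencies(law.alpha, law.k, n)


def synthetic_category_labels(n: int) -> list[str]:
    """Deterministic ICD-10-shaped labels for n synthetic categories.

    Rank r maps to letter ``(r-1) mod 25`` of A..Y (Z excluded) and a
    two-digit suffix ``(r-1) div 25``: A00, B00, ..., Y00, A01, B01, ...
    All labels are valid 3-character categories, so the preprocessing stage
    runs unmodified on synthetic data.
    """
    labels = []
    for r in range(n):
        letter = _NON_Z_LETTERS[r % len(_NON_Z_LETTERS)]
        labels.append(f"{letter}{r // len(_NON_Z_LETTERS):02d}")
    return labels


def _rounded_counts(expected: np.ndarray) -> np.ndarray:
    # Round half to even, with a floor of 1 so every category stays present
    # (a zero-count category would silently change n between configurations).
    return np.maximum(np.rint(expected), 1.0).astype(int)


def generate_admissions(config: SimulationConfig) -> list[AdmissionRecord]:
    """Synthesize the admission stream for every configured year.

    With ``noise="none"`` per-category annual counts are the expected counts
    rounded (half to even, floored at 1); with ``noise="poisson"`` they are
    Poisson draws with the expected counts as means. Z-chapter contamination
    is appended per year so that the Z share of the whole stream matches
    ``z_fraction`` (exactly under no noise, in expectation under Poisson).
    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    labels = synthetic_category_labels(config.law.n_categories)
    base = expected_counts(config.law)

    records: list[AdmissionRecord] = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"SYN{serial:07d}"

    zf = config.z_fraction
    for year in config.years:
        expected = base * config.year_factors.get(year, 1.0)
        if config.noise == "none":
            counts = _rounded_counts(expected)
            z_total = int(np.rint(counts.sum() * zf / (1.0 - zf))) if zf > 0 else 0
        else:
            counts = rng.poisson(expected)
            z_mean = expected.sum() * zf / (1.0 - zf)
            z_total = int(rng.poisson(z_mean)) if zf > 0 else 0

        for label, count in zip(labels, counts):
            for _ in range(int(count)):
                records.append(AdmissionRecord(next_id(), label, year))
        for i in range(z_total):
            records.append(AdmissionRecord(next_id(), _Z_CODES[i % len(_Z_CODES)], year))
    return records


def write_simulation(
    config: SimulationConfig,
    csv_path: str | Path,
    meta_path: str | Path | None = None,
) -> list[AdmissionRecord]:
    """Generate a stream, write it as CSV, and drop a JSON metadata sidecar.

    The sidecar records the full configuration (seed included) so the stream
    can be regenerated byte-identically.
    """
    from .icd_processing import write_admissions_csv

    records = generate_admissions(config)
    write_admissions_csv(records, csv_path)
    if meta_path is None:
        meta_path = Path(csv_path).with_suffix(".meta.json")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump({"config": config.to_dict(), "n_records": len(records)}, fh, indent=2)
        fh.write("\n")
    return records
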