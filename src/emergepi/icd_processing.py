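"""ICD-10 discharge-code preprocessing for emergency-admission streams.

Codes are normalized to the 3-character ICD-10 *category* (letter + two
digits, e.g. ``I21``), grouped into capital-letter chapter groups with the
infectious-disease letters A and B merged into a single ``A/B`` group,
filtered of Z-chapter discharges (factors influencing health status, by
definition not emergencies), and optionally classified into the surgical or
medical arm of a hospital duty roster via an editable mapping.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

logger = logging.getLogger("emergepi")

RosterLabel = Literal["surgical", "medical", "unassigned"]

#: Lexical shape of an ICD-10 code: one capital letter, two digits, then
#: optionally more detail characters (with or without the customary dot).
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[0-9A-Z]+)?$")


class InvalidCodeError(ValueError):
    """Raised when a string does not have the ICD-10 lexical shape."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"not an ICD-10 code: {raw!r}")


@dataclass(frozen=True)
class AdmissionRecord:
    """One emergency admission: who, with what main discharge diagnosis, when."""

    patient_id: str
    icd10_code: str
    year: int
    roster: RosterLabel | None = None


@dataclass(frozen=True)
class DiagnosisCategory:
    """A 3-character ICD-10 category together with its chapter-letter group."""

    code: str
    chapter_group: str = field(init=False)

    def __post_init__(self):
        if len(self.code) != 3 or not _ICD10_RE.match(self.code):
            raise InvalidCodeError(self.code)
        object.__setattr__(self, "chapter_group", chapter_of(self.code))


def parse_code(raw: str) -> str:
    """Normalize and validate a raw ICD-10 code string.

    Uppercases and strips surrounding whitespace; anything that then fails
    the ICD-10 lexical shape (letter, two digits, optional detail suffix)
    raises :class:`InvalidCodeError` carrying the offending string.
    """
    code = str(raw).strip().upper()
    if not _ICD10_RE.match(code):
        raise InvalidCodeError(raw)
    return code


def truncate_code(code: str) -> str:
    """Truncate a parsed ICD-10 code to its 3-character category.

    The 4th and later characters only encode detail (e.g. where in the
    breast a breast cancer sits), so category-level analysis drops them.
    Idempotent: a 3-character code is returned unchanged.
    """
    return code[:3]


def chapter_of(category: str) -> str:
    """Capital-letter chapter group of a category; A and B merge into ``A/B``.

    Grouping is by first letter of the code (so C and D stay separate
    entities), not by the official ICD-10 letter-range chapters.
    """
    first = category[0]
    return "A/B" if first in ("A", "B") else first


def exclude_z(
    records: Iterable[AdmissionRecord],
) -> tuple[list[AdmissionRecord], int]:
    """Drop Z-chapter discharges (non-emergencies by definition).

    Returns ``(retained, excluded_count)``; retained + excluded equals the
    input count, always.
    """
    retained: list[AdmissionRecord] = []
    excluded = 0
    for rec in records:
        if rec.icd10_code[0] == "Z":
            excluded += 1
        else:
            retained.append(rec)
    return retained, excluded


# ---------------------------------------------------------------------------
# Duty-roster classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RosterMapping:
    """Chapter-level roster assignments with category-level overrides.

    The split between surgical and medical duty-roster arms reflects local
    hospital routines, so the mapping ships as an editable YAML file rather
    than a hard-coded rule.
    """

    chapters: dict[str, str]
    categories: dict[str, str]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RosterMapping":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls._from_dict(raw, source=str(path))

    @classmethod
    def default(cls) -> "RosterMapping":
        """The mapping shipped with the package (editable YAML resource)."""
        text = (
            resources.files("emergepi").joinpath("data/roster_mapping.yaml").read_text()
        )
        return cls._from_dict(yaml.safe_load(text), source="<default>")

    @classmethod
    def empty(cls) -> "RosterMapping":
        return cls(chapters={}, categories={})

    @classmethod
    def _from_dict(cls, raw: dict, source: str) -> "RosterMapping":
        chapters = {str(k): str(v) for k, v in (raw.get("chapters") or {}).items()}
        categories = {str(k): str(v) for k, v in (raw.get("categories") or {}).items()}
        for where, table in (("chapters", chapters), ("categories", categories)):
            for key, label in table.items():
                if label not in ("surgical", "medical"):
                    raise ValueError(
                        f"{source}: {where}[{key!r}] = {label!r}; "
                        "labels must be 'surgical' or 'medical'"
                    )
        return cls(chapters=chapters, categories=categories)


def classify_roster(category: str, mapping: RosterMapping) -> RosterLabel:
    """Assign a category to the surgical or medical duty-roster arm.

    Category-level entries override chapter-level entries; a category with
    no entry at either level is labelled ``unassigned`` with a warning.
    """
    if category in mapping.categories:
        return mapping.categories[category]  # type: ignore[return-value]
    group = chapter_of(category)
    if group in mapping.chapters:
        return mapping.chapters[group]  # type: ignore[return-value]
    logger.warning("no roster mapping entry for category %s (group %s)", category, group)
    return "unassigned"


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------


def preprocess(
    records: Iterable[AdmissionRecord],
    on_malformed: Literal["drop", "strict"] = "drop",
    roster_mapping: RosterMapping | None = None,
) -> tuple[list[AdmissionRecord], int, int]:
    """Parse, truncate, Z-filter and roster-classify an admission stream.

    Returns ``(retained, z_excluded, malformed_dropped)``; every input
    record lands in exactly one of the three buckets. With
    ``on_malformed='strict'`` the first malformed code aborts instead.
    Retained records carry the 3-character category as their code and, when
    a mapping is given, a roster label.
    """
    parsed: list[AdmissionRecord] = []
    malformed = 0
    for rec in records:
        try:
            code = truncate_code(parse_code(rec.icd10_code))
        except InvalidCodeError:
            if on_malformed == "strict":
                raise
            malformed += 1
            logger.warning(
                "dropping record %s: malformed code %r", rec.patient_id, rec.icd10_code
            )
            continue
        roster = rec.roster
        if roster_mapping is not None:
            roster = classify_roster(code, roster_mapping)
        parsed.append(
            AdmissionRecord(
                patient_id=rec.patient_id, icd10_code=code, year=rec.year, roster=roster
            )
        )
    retained, z_excluded = exclude_z(parsed)
    return retained, z_excluded, malformed


def read_admissions_csv(path: str | Path) -> list[AdmissionRecord]:
    """Read an admission stream from CSV: ``patient_id,icd10_code,year[,roster]``."""
    records: list[AdmissionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "icd10_code", "year"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: CSV header must contain {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            roster = row.get("roster") or None
            records.append(
                AdmissionRecord(
                    patient_id=row["patient_id"],
                    icd10_code=row["icd10_code"],
                    year=int(row["year"]),
                    roster=roster,  # type: ignore[arg-type]
                )
            )
    return records


def write_admissions_csv(records: Sequence[AdmissionRecord], path: str | Path) -> None:
    """Write an admission stream as CSV with the standard header."""
    has_roster = any(r.roster is not None for r in records)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["patient_id", "icd10_code", "year"] + (["roster"] if has_roster else [])
        writer.writerow(header)
        for r in records:
            row = [r.patient_id, r.icd10_code, str(r.year)]
            if has_roster:
                row.append(r.roster or "")
            writer.writerow(row)
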