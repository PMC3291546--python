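"""Sample data model, tidy-table IO, design validation, and elementary conversions.

The unit record is one tissue measurement of one individual in the
two-dimensional isotope plane (d13C in per-mil vs PDB, d15N in per-mil vs
air).  Everything downstream (metrics, inference, reporting) consumes
samples only through :class:`SampleSet`.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "HABITATS",
    "AGES",
    "TISSUES",
    "UNDEFINED_HABITAT",
    "DEFAULT_COLUMNS",
    "IsotopeSample",
    "SampleSet",
    "Violation",
    "ValidationReport",
    "IsotopeRatioPair",
    "ParseError",
    "delta_from_ratios",
    "classify_habitat",
    "read_sample_table",
    "validate_sample_set",
    "write_table",
    "write_sample_table",
]

#: Closed vocabularies.  Unknown labels are rejected, never coerced.
HABITATS = ("coastal", "inland")
AGES = ("adult", "juvenile")
TISSUES = ("fur", "muscle", "collagen")

#: Label for shore distances falling in the gap between the coastal and
#: inland definitions; such animals are excluded from analysis.
UNDEFINED_HABITAT = "undefined"

#: Default column names of the tidy sample table (header row required).
DEFAULT_COLUMNS: Mapping[str, str] = {
    "individual_id": "individual_id",
    "province": "province",
    "habitat": "habitat",
    "age": "age",
    "tissue": "tissue",
    "d13c": "d13C",
    "d15n": "d15N",
    "collection_date": "date",
}

_REQUIRED_FIELDS = ("individual_id", "province", "habitat", "age", "tissue", "d13c", "d15n")


class ParseError(ValueError):
    """Structured table-parsing failure naming the offending row.

    ``row`` is the 1-based data-row number (header excluded); ``None`` for
    file-level problems such as a missing column.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        suffix = f" (row {row})" if row is not None else ""
        super().__init__(message + suffix)


@dataclass(frozen=True)
class IsotopeSample:
    """One tissue measurement of one individual."""

    individual_id: str
    province: str
    habitat: str
    age: str
    tissue: str
    d13c: float
    d15n: float
    collection_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat label {self.habitat!r}; expected one of {HABITATS}")
        if self.age not in AGES:
            raise ValueError(f"unknown age label {self.age!r}; expected one of {AGES}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue label {self.tissue!r}; expected one of {TISSUES}")
        for name in ("d13c", "d15n"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")

    @property
    def point(self) -> tuple[float, float]:
        """(d13C, d15N) position in the isotope plane, per-mil."""
        return (self.d13c, self.d15n)


@dataclass(frozen=True)
class SampleSet:
    """Ordered, immutable collection of samples with a provenance note."""

    samples: tuple[IsotopeSample, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[IsotopeSample]:
        return iter(self.samples)

    def individuals(self) -> list[str]:
        """Distinct individual ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.individual_id, None)
        return list(seen)

    def for_individual(self, individual_id: str) -> list[IsotopeSample]:
        return [s for s in self.samples if s.individual_id == individual_id]

    def subset(self, *, habitat: str | None = None, age: str | None = None,
               tissue: str | None = None) -> "SampleSet":
        keep = [
            s for s in self.samples
            if (habitat is None or s.habitat == habitat)
            and (age is None or s.age == age)
            and (tissue is None or s.tissue == tissue)
        ]
        return SampleSet(tuple(keep), provenance=self.provenance)

    def restrict_dates(self, start: _dt.date | None, end: _dt.date | None) -> "SampleSet":
        """Keep samples whose collection date falls in [start, end].

        Samples without a date are retained (months were pooled in the
        source design; the window is an opt-in restriction).
        """
        keep = []
        for s in self.samples:
            d = s.collection_date
            if d is None:
                keep.append(s)
            elif (start is None or d >= start) and (end is None or d <= end):
                keep.append(s)
        return SampleSet(tuple(keep), provenance=self.provenance)


@dataclass(frozen=True)
class Violation:
    code: str
    row: int | None
    message: str


@dataclass
class ValidationReport:
    n_individuals: int
    n_samples: int
    group_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_text(self) -> str:
        lines = [f"samples: {self.n_samples}", f"individuals: {self.n_individuals}"]
        for key in sorted(self.group_counts):
            lines.append(f"  {key[0]} / {key[1]} / {key[2]}: {self.group_counts[key]}")
        if self.violations:
            lines.append(f"violations: {len(self.violations)}")
            for v in self.violations:
                where = f" row {v.row}" if v.row is not None else ""
                lines.append(f"  [{v.code}]{where}: {v.message}")
        else:
            lines.append("violations: none")
        return "\n".join(lines)


@dataclass(frozen=True)
class IsotopeRatioPair:
    """Raw heavy/light isotope ratios of a sample and its standard."""

    r_sample: float
    r_standard: float

    def __post_init__(self) -> None:
        for name in ("r_sample", "r_standard"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")


def delta_from_ratios(pair: IsotopeRatioPair) -> float:
    """Per-mil deviation of a sample ratio from its standard.

    Returns ``1000 * (r_sample / r_standard - 1)``.
    """
    return 1000.0 * (pair.r_sample / pair.r_standard - 1.0)


def classify_habitat(distance_to_shore_km: float) -> str:
    """Label a location by shore distance: <=3 km coastal, >=10 km inland.

    Distances strictly between 3 and 10 km fall in the gap left by the two
    definitions and map to :data:`UNDEFINED_HABITAT`.
    """
    d = float(distance_to_shore_km)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"distance to shore must be finite and non-negative, got {d!r}")
    if d <= 3.0:
        return "coastal"
    if d >= 10.0:
        return "inland"
    return UNDEFINED_HABITAT


def _parse_date(text: str, row: int) -> _dt.date | None:
    text = text.strip()
    if not text:
        return None
    try:
        return _dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ParseError(f"unparseable date {text!r}: {exc}", row=row) from None


def read_sample_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
) -> SampleSet:
    """Read a delimited tidy sample table into a :class:`SampleSet`.

    Parameters
    ----------
    path:
        UTF-8 text file with a header row.
    delimiter:
        Field delimiter; ``","`` (default) or ``"\\t"``.
    columns:
        Optional mapping from canonical field names (keys of
        :data:`DEFAULT_COLUMNS`) to the header names used in the file.

    Raises
    ------
    ParseError
        On missing required columns, unparseable values, unknown factor
        labels or duplicated (individual, tissue) pairs — always naming the
        1-based data row where applicable.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ParseError("empty file: no header row")
        header = set(reader.fieldnames)
        for field_name in _REQUIRED_FIELDS:
            if colmap[field_name] not in header:
                raise ParseError(f"missing required column {colmap[field_name]!r}")
        has_date = colmap["collection_date"] in header

        samples: list[IsotopeSample] = []
        seen: set[tuple[str, str]] = set()
        for row_no, row in enumerate(reader, start=1):
            raw = {f: (row.get(colmap[f]) or "").strip() for f in _REQUIRED_FIELDS}
            try:
                d13c = float(raw["d13c"])
                d15n = float(raw["d15n"])
            except ValueError:
                raise ParseError(
                    f"unparseable isotope value d13C={raw['d13c']!r} d15N={raw['d15n']!r}",
                    row=row_no,
                ) from None
            date = _parse_date(row.get(colmap["collection_date"], ""), row_no) if has_date else None
            try:
                sample = IsotopeSample(
                    individual_id=raw["individual_id"],
                    province=raw["province"],
                    habitat=raw["habitat"],
                    age=raw["age"],
                    tissue=raw["tissue"],
                    d13c=d13c,
                    d15n=d15n,
                    collection_date=date,
                )
            except ValueError as exc:
                raise ParseError(str(exc), row=row_no) from None
            key = (sample.individual_id, sample.tissue)
            if key in seen:
                raise ParseError(
                    f"duplicate (individual, tissue) pair {key!r}", row=row_no
                )
            seen.add(key)
            samples.append(sample)

    return SampleSet(tuple(samples), provenance=str(path))


def validate_sample_set(s: SampleSet) -> ValidationReport:
    """Check cross-sample invariants; violations are reported, not raised.

    Checks: unique (individual, tissue) pairs, and constant habitat / age /
    province within each individual.  Rows are 1-based positions in the set.
    """
    violations: list[Violation] = []
    seen: dict[tuple[str, str], int] = {}
    factors: dict[str, tuple[str, str, str, int]] = {}
    group_counts: dict[tuple[str, str, str], int] = {}

    for row_no, sample in enumerate(s, start=1):
        key = (sample.individual_id, sample.tissue)
        if key in seen:
            violations.append(
                Violation(
                    code="duplicate_sample",
                    row=row_no,
                    message=f"(individual, tissue) {key!r} already seen at row {seen[key]}",
                )
            )
        else:
            seen[key] = row_no

        fkey = (sample.habitat, sample.age, sample.province)
        prior = factors.get(sample.individual_id)
        if prior is None:
            factors[sample.individual_id] = (*fkey, row_no)
        elif prior[:3] != fkey:
            violations.append(
                Violation(
                    code="inconsistent_individual_factors",
                    row=row_no,
                    message=(
                        f"individual {sample.individual_id!r} has "
                        f"(habitat, age, province)={fkey!r} here but "
                        f"{prior[:3]!r} at row {prior[3]}"
                    ),
                )
            )
        gkey = (sample.habitat, sample.age, sample.tissue)
        group_counts[gkey] = group_counts.get(gkey, 0) + 1

    return ValidationReport(
        n_individuals=len(factors),
        n_samples=len(s),
        group_counts=group_counts,
        violations=violations,
    )


def write_sample_table(s: SampleSet, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a SampleSet back to the tidy-table dialect of
    :func:`read_sample_table` (delta values kept to full float precision)."""
    if len(s) == 0:
        raise ValueError("refusing to write an empty SampleSet")
    rows = []
    for sample in s:
        rows.append(
            {
                DEFAULT_COLUMNS["individual_id"]: sample.individual_id,
                DEFAULT_COLUMNS["province"]: sample.province,
                DEFAULT_COLUMNS["habitat"]: sample.habitat,
                DEFAULT_COLUMNS["age"]: sample.age,
                DEFAULT_COLUMNS["tissue"]: sample.tissue,
                DEFAULT_COLUMNS["d13c"]: repr(sample.d13c),
                DEFAULT_COLUMNS["d15n"]: repr(sample.d15n),
                DEFAULT_COLUMNS["collection_date"]: (
                    sample.collection_date.isoformat() if sample.collection_date else ""
                ),
            }
        )
    write_table(rows, path, delimiter=delimiter)


def write_table(
    records: Sequence[Mapping[str, object]] | Iterable[Mapping[str, object]],
    path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write a sequence of homogeneous mappings as a delimited text table."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty table")
    fieldnames = list(records[0].keys())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter=delimiter)
        writer.writeheader()
        for rec in records:
            writer.writerow(rec)
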