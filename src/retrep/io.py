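"""Domain types and table I/O for repeated per-image trait measurements.

The analysis unit throughout the package is the *eye*: all repeated images
of one eye form an :class:`EyeSeries`, and a named collection of eye series
is a :class:`CohortTable`.  Input is a delimited text table with one row
per image carrying subject/eye/image identifiers, an acquisition
timestamp, one column per measurement method (e.g. the fractal dimension
produced by two different tools), and a continuous image-quality score
``quality_pbad`` — the probability in [0, 1] that the image is of bad
quality.

Rows with a missing trait value for some method are retained (the image
may still carry other methods' values) and simply ignored when that
method is analysed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .errors import RecordValidationError, TableSchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "ImageRecord",
    "EyeSeries",
    "CohortTable",
    "TableSchema",
    "read_measurement_table",
    "filter_min_images",
    "write_results",
    "read_results_table",
    "write_json_summary",
]


class TableSchema(BaseModel):
    """Column-name mapping for the measurement table.

    ``trait_columns`` maps method name -> column name.  When empty, every
    column not claimed by the five required fields is treated as a trait
    column for a method of the same name.
    """

    subject_id: str = "subject_id"
    eye: str = "eye"
    image_id: str = "image_id"
    acquired_at: str = "acquired_at"
    quality_pbad: str = "quality_pbad"
    trait_columns: dict[str, str] = Field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableSchema":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def required_columns(self) -> list[str]:
        return [self.subject_id, self.eye, self.image_id, self.acquired_at, self.quality_pbad]


@dataclass(frozen=True)
class ImageRecord:
    """One image's measurement: identifiers, timestamp, per-method trait
    values and the quality score P(bad)."""

    subject_id: str
    eye: str
    image_id: str
    acquired_at: pd.Timestamp
    trait_values: Mapping[str, float]
    quality_pbad: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.quality_pbad <= 1.0):
            raise RecordValidationError(
                f"image {self.image_id!r}: quality_pbad={self.quality_pbad} outside [0, 1]"
            )
        for method, value in self.trait_values.items():
            if not math.isfinite(value) or value <= 0:
                raise RecordValidationError(
                    f"image {self.image_id!r}: trait {method!r}={value} not finite and > 0"
                )

    def value(self, method: str) -> float | None:
        """Trait value for ``method``, or None when missing."""
        return self.trait_values.get(method)


@dataclass(frozen=True)
class EyeSeries:
    """All images of one eye, ascending by acquisition time (ties broken by
    image id)."""

    subject_id: str
    eye: str
    records: tuple[ImageRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise RecordValidationError(f"eye ({self.subject_id}, {self.eye}): no records")
        for r in self.records:
            if (r.subject_id, r.eye) != (self.subject_id, self.eye):
                raise RecordValidationError(
                    f"record {r.image_id!r} does not belong to eye ({self.subject_id}, {self.eye})"
                )
        ordered = tuple(sorted(self.records, key=lambda r: (r.acquired_at, r.image_id)))
        object.__setattr__(self, "records", ordered)

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.eye)

    @property
    def n_images(self) -> int:
        return len(self.records)

    def usable_records(self, method: str) -> list[ImageRecord]:
        """Records carrying a value for ``method``, in time order."""
        return [r for r in self.records if method in r.trait_values]

    def values(self, method: str) -> list[float]:
        return [r.trait_values[method] for r in self.usable_records(method)]


@dataclass
class CohortTable:
    """A named collection of eye series (one dataset)."""

    name: str
    eyes: list[EyeSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.eyes]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise RecordValidationError(f"cohort {self.name!r}: duplicated eye keys {dupes}")
        image_ids = [r.image_id for e in self.eyes for r in e.records]
        if len(image_ids) != len(set(image_ids)):
            raise RecordValidationError(f"cohort {self.name!r}: duplicated image ids")

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)

    @property
    def n_images(self) -> int:
        return sum(e.n_images for e in self.eyes)

    @property
    def methods(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.eyes:
            for r in e.records:
                for m in r.trait_values:
                    seen.setdefault(m)
        return list(seen)

    def iter_records(self) -> Iterable[ImageRecord]:
        for e in self.eyes:
            yield from e.records

    @classmethod
    def from_records(cls, name: str, records: Iterable[ImageRecord]) -> "CohortTable":
        """Group records by (subject_id, eye) into time-sorted eye series."""
        grouped: dict[tuple[str, str], list[ImageRecord]] = {}
        for r in records:
            grouped.setdefault((r.subject_id, r.eye), []).append(r)
        eyes = [
            EyeSeries(subject_id=k[0], eye=k[1], records=tuple(v))
            for k, v in sorted(grouped.items())
        ]
        return cls(name=name, eyes=eyes)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per image; trait columns named after methods."""
        methods = self.methods
        rows = []
        for r in self.iter_records():
            row = {
                "subject_id": r.subject_id,
                "eye": r.eye,
                "image_id": r.image_id,
                "acquired_at": r.acquired_at,
                "quality_pbad": r.quality_pbad,
            }
            for m in methods:
                row[m] = r.trait_values.get(m, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_measurement_table(
    path: str | Path,
    schema: TableSchema | None = None,
    name: str | None = None,
) -> CohortTable:
    """Read a per-image measurement table into a :class:`CohortTable`.

    CSV/TSV is autodetected from the file extension.  Raises
    :class:`TableSchemaError` when a required column is missing and
    :class:`RecordValidationError` for out-of-range quality scores or
    unparsable timestamps, citing the offending row.
    """
    path = Path(path)
    schema = schema or TableSchema()
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in schema.required_columns():
        if col not in df.columns:
            raise TableSchemaError(f"{path.name}: missing required column {col!r}")

    trait_columns = dict(schema.trait_columns)
    if not trait_columns:
        claimed = set(schema.required_columns())
        trait_columns = {c: c for c in df.columns if c not in claimed}

    for method, col in trait_columns.items():
        if col not in df.columns:
            raise TableSchemaError(f"{path.name}: missing trait column {col!r} for method {method!r}")

    timestamps = pd.to_datetime(df[schema.acquired_at], errors="coerce", format="mixed")
    n_flagged = 0
    records: list[ImageRecord] = []
    for i, row in df.iterrows():
        ts = timestamps.iloc[i]
        if pd.isna(ts):
            raise RecordValidationError(
                f"{path.name} row {i}: unparsable timestamp {row[schema.acquired_at]!r}"
            )
        pbad = float(row[schema.quality_pbad])
        if not (0.0 <= pbad <= 1.0):
            raise RecordValidationError(
                f"{path.name} row {i}: quality_pbad={pbad} outside [0, 1]"
            )
        traits: dict[str, float] = {}
        for method, col in trait_columns.items():
            v = row[col]
            if pd.isna(v):
                n_flagged += 1
                continue
            traits[method] = float(v)
        records.append(
            ImageRecord(
                subject_id=str(row[schema.subject_id]),
                eye=str(row[schema.eye]),
                image_id=str(row[schema.image_id]),
                acquired_at=ts,
                trait_values=traits,
                quality_pbad=pbad,
            )
        )
    if n_flagged:
        logger.info("%s: %d missing trait values flagged (rows retained)", path.name, n_flagged)
    cohort = CohortTable.from_records(name or path.stem, records)
    logger.info(
        "read %s: %d images grouped into %d eyes", path.name, cohort.n_images, cohort.n_eyes
    )
    return cohort


def filter_min_images(cohort: CohortTable, min_n: int) -> CohortTable:
    """Keep only eyes with at least ``min_n`` images (e.g. the study design
    rule of at least five images per eye)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept = [e for e in cohort.eyes if e.n_images >= min_n]
    removed = cohort.n_eyes - len(kept)
    if removed:
        logger.info(
            "filter_min_images(%d): removed %d of %d eyes from %s",
            min_n, removed, cohort.n_eyes, cohort.name,
        )
    return CohortTable(name=cohort.name, eyes=kept)


def _rows_for(results: Sequence) -> list[dict]:
    rows = []
    for r in results:
        to_row = getattr(r, "to_row", None)
        rows.append(to_row() if callable(to_row) else dict(r))
    return rows


def write_results(results: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Serialize a homogeneous list of result objects (or a DataFrame) to
    delimited text.  Floats are written with enough digits to round-trip."""
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(_rows_for(results))
    df.to_csv(path, index=False, sep=_sep_for(path), float_format="%.17g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def write_json_summary(summary: dict, path: str | Path) -> None:
    """Write a machine-readable run summary (deterministic key order)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
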