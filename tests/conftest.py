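"""Shared fixtures: small hand-built cohorts and builders.

All fixtures are generated programmatically; nothing is read from disk
except temporary files the tests themselves write.
"""

from __future__ import annotations

import pandas as pd
import pytest

from retrep.io import CohortTable, EyeSeries, ImageRecord


def make_record(
    subject: str,
    eye: str,
    image_id: str,
    t: str | pd.Timestamp,
    values: dict[str, float],
    pbad: float = 0.1,
) -> ImageRecord:
    return ImageRecord(
        subject_id=subject,
        eye=eye,
        image_id=image_id,
        acquired_at=pd.Timestamp(t),
        trait_values=values,
        quality_pbad=pbad,
    )


def make_eye(
    subject: str,
    eye: str,
    values: list[float],
    method: str = "FD",
    pbads: list[float] | None = None,
    start: str = "2022-01-01",
) -> EyeSeries:
    pbads = pbads if pbads is not None else [0.1] * len(values)
    t0 = pd.Timestamp(start)
    records = tuple(
        make_record(
            subject, eye, f"{subject}_{eye}_{i:02d}",
            t0 + pd.Timedelta(minutes=5 * i), {method: v}, pbad=p,
        )
        for i, (v, p) in enumerate(zip(values, pbads))
    )
    return EyeSeries(subject_id=subject, eye=eye, records=records)


def make_cohort(
    eye_values: dict[tuple[str, str], list[float]],
    method: str = "FD",
    pbads: dict[tuple[str, str], list[float]] | None = None,
    name: str = "toy",
) -> CohortTable:
    eyes = [
        make_eye(s, e, vals, method=method, pbads=(pbads or {}).get((s, e)))
        for (s, e), vals in eye_values.items()
    ]
    return CohortTable(name=name, eyes=eyes)


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Five eyes with hand-written values; varied sizes and quality."""
    return make_cohort(
        {
            ("S1", "right"): [1.50, 1.52, 1.48, 1.51],
            ("S1", "left"): [1.60, 1.61, 1.59],
            ("S2", "right"): [1.40, 1.42],
            ("S3", "right"): [1.55, 1.53, 1.56, 1.54, 1.55],
            ("S4", "left"): [1.45, 1.47, 1.44],
        },
        pbads={
            ("S1", "right"): [0.05, 0.10, 0.70, 0.20],
            ("S1", "left"): [0.15, 0.30, 0.10],
            ("S2", "right"): [0.50, 0.05],
            ("S3", "right"): [0.10, 0.20, 0.85, 0.05, 0.15],
            ("S4", "left"): [0.25, 0.10, 0.40],
        },
    )
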