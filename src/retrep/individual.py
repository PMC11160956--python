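"""Individual-level measurement noise: the relative-SD statistic λ.

For a single eye, λ is the within-eye sample SD of the trait expressed
in units of a reference between-eyes SD:

.. math:: \\lambda = \\frac{\\mathrm{SD~within~eye}}{\\mathrm{SD~across~eyes}} \\times 100\\%

λ = 0 means the repeated measurements of that eye are identical; λ near
100% means the eye's own measurement scatter is as large as the spread
of true values across the population, so the measurement carries
essentially no individual-level information.  Because the SD squares
deviations, a single grossly wrong image (e.g. a badly illuminated
fundus photograph) can dominate an eye's λ — which is why the worst
image quality in the eye is carried alongside each λ.

The reference SD should come from a heterogeneous population (here: the
combined cohorts) so that λ values are comparable across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .io import CohortTable, EyeSeries

logger = logging.getLogger(__name__)

__all__ = ["LambdaResult", "LambdaSummary", "lambda_per_eye", "lambda_distribution"]


@dataclass(frozen=True)
class LambdaResult:
    """λ for one eye: within-eye SD over reference between-eyes SD, in %."""

    subject_id: str
    eye: str
    method: str
    lambda_pct: float
    n_images: int
    worst_pbad: float

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "eye": self.eye,
            "method": self.method,
            "lambda_pct": self.lambda_pct,
            "n_images": self.n_images,
            "worst_pbad": self.worst_pbad,
        }


@dataclass(frozen=True)
class LambdaSummary:
    """Five-number summary of a cohort's λ distribution (percent)."""

    method: str
    n_eyes: int
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("quantiles out of order")

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "n_eyes": self.n_eyes,
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
        }


def lambda_per_eye(series: EyeSeries, method: str, reference_sd: float) -> LambdaResult:
    """λ for one eye series.

    Requires at least two usable images (a within-eye SD from one image
    would be fabricated) and a strictly positive reference SD.  The
    within-eye SD uses the sample (n − 1) denominator, consistent with
    the population-level estimators.
    """
    if reference_sd <= 0:
        raise AnalysisError(f"reference_sd must be > 0, got {reference_sd}")
    usable = series.usable_records(method)
    if len(usable) < 2:
        raise AnalysisError(
            f"eye {series.key}: {len(usable)} usable images for {method!r}; need >= 2"
        )
    values = np.asarray([r.trait_values[method] for r in usable], dtype=float)
    # identical values must give exactly 0 (the rounding in the mean of n
    # equal floats would otherwise leak a ~1e-13 lambda)
    sd_within = 0.0 if np.all(values == values[0]) else float(values.std(ddof=1))
    return LambdaResult(
        subject_id=series.subject_id,
        eye=series.eye,
        method=method,
        lambda_pct=100.0 * sd_within / reference_sd,
        n_images=len(usable),
        worst_pbad=max(r.quality_pbad for r in usable),
    )


def lambda_distribution(
    cohort: CohortTable,
    method: str,
    reference_sd: float,
    min_images: int = 2,
) -> tuple[list[LambdaResult], LambdaSummary]:
    """λ for every eligible eye plus a five-number summary.

    Eyes with fewer than ``min_images`` usable images are reported as
    ineligible (skipped with a log line) rather than assigned λ = 0,
    which would understate their noise.  Quartiles use linear
    interpolation.
    """
    min_images = max(min_images, 2)
    results: list[LambdaResult] = []
    n_skipped = 0
    for eye in cohort.eyes:
        if len(eye.usable_records(method)) < min_images:
            n_skipped += 1
            continue
        results.append(lambda_per_eye(eye, method, reference_sd))
    if n_skipped:
        logger.info(
            "lambda_distribution(%s, %s): %d ineligible eyes (<%d usable images)",
            cohort.name, method, n_skipped, min_images,
        )
    if not results:
        raise AnalysisError(f"no eligible eyes for {method!r} in cohort {cohort.name!r}")
    lam = np.asarray([r.lambda_pct for r in results])
    q1, med, q3 = np.quantile(lam, [0.25, 0.5, 0.75])
    summary = LambdaSummary(
        method=method,
        n_eyes=len(results),
        min=float(lam.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(lam.max()),
    )
    return results, summary
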