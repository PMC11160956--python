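"""Robustness of repeatability to image quality.

Three analyses relate measurement noise to the image-quality score
P(bad):

* a hard quality gate (drop images with P(bad) above a threshold);
* an exclusion sweep: remove the worst x% of images cohort-wide for x
  from 0 to 50% and track how the λ distribution responds — a single
  gross outlier image inflates its eye's λ enormously, so modest
  exclusions should collapse the maximum while barely moving the median;
* correlation of λ with the worst P(bad) in each eye, on the probability
  scale and on the logit scale.  The logit is the quality model's raw
  output; probabilities saturate near 1 while λ keeps growing, so the
  logit tends to be the better *linear* predictor.  Spearman is
  invariant under the (monotone) logistic link, which is checked at
  runtime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError
from .individual import LambdaResult, lambda_distribution
from .io import CohortTable, EyeSeries
from .population import CorrelationResult, PairingTable, correlation

logger = logging.getLogger(__name__)

__all__ = [
    "SweepRow",
    "exclude_worst_fraction",
    "exclusion_sweep",
    "apply_quality_threshold",
    "lambda_quality_correlation",
    "logit",
]

_LOGIT_EPS = 1e-6

DEFAULT_SWEEP_FRACTIONS = tuple(round(0.05 * k, 2) for k in range(11))  # 0, 0.05, ..., 0.50


def logit(p: np.ndarray | float) -> np.ndarray | float:
    """log(p / (1 - p)) with p clipped to [1e-6, 1 - 1e-6]."""
    p = np.clip(p, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class SweepRow:
    """λ distribution after excluding the worst ``exclusion_fraction`` of
    images cohort-wide."""

    exclusion_fraction: float
    pbad_cutoff: float | None  # P(bad) of the mildest excluded image; None at 0%
    n_images_retained: int
    n_eyes_eligible: int
    lambda_min: float
    lambda_median: float
    lambda_max: float

    def to_row(self) -> dict:
        return {
            "exclusion_fraction": self.exclusion_fraction,
            "pbad_cutoff": self.pbad_cutoff,
            "n_images_retained": self.n_images_retained,
            "n_eyes_eligible": self.n_eyes_eligible,
            "lambda_min": self.lambda_min,
            "lambda_median": self.lambda_median,
            "lambda_max": self.lambda_max,
        }


def _rebuild(cohort: CohortTable, keep) -> CohortTable:
    """New cohort keeping records for which ``keep(record)`` is true;
    eyes emptied entirely are dropped."""
    eyes = []
    for eye in cohort.eyes:
        records = tuple(r for r in eye.records if keep(r))
        if records:
            eyes.append(EyeSeries(subject_id=eye.subject_id, eye=eye.eye, records=records))
    return CohortTable(name=cohort.name, eyes=eyes)


def exclude_worst_fraction(cohort: CohortTable, fraction: float) -> CohortTable:
    """Remove the worst ``ceil(fraction * N)`` images cohort-wide.

    Images are ranked by ``quality_pbad`` descending with ties broken by
    image id, so the exclusion is deterministic.  The ceiling means any
    nonzero fraction removes at least one image.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n_total = cohort.n_images
    k = math.ceil(fraction * n_total)
    if k == 0:
        return cohort
    ranked = sorted(cohort.iter_records(), key=lambda r: (-r.quality_pbad, r.image_id))
    excluded_ids = {r.image_id for r in ranked[:k]}
    return _rebuild(cohort, lambda r: r.image_id not in excluded_ids)


def exclusion_sweep(
    cohort: CohortTable,
    method: str,
    reference_sd: float,
    fractions: Sequence[float] = DEFAULT_SWEEP_FRACTIONS,
    min_images: int = 2,
) -> list[SweepRow]:
    """Recompute the λ distribution at each exclusion fraction.

    ``reference_sd`` is held fixed across the sweep so λ values stay
    comparable between rows.  Eyes falling below ``min_images`` usable
    images at some fraction drop out of that row's distribution; a
    fraction leaving no eligible eye yields a flagged (NaN) row rather
    than an error.
    """
    fr = [float(f) for f in fractions]
    if any(f < 0 or f > 0.5 for f in fr):
        raise ValueError("sweep fractions must lie in [0, 0.5]")
    if sorted(fr) != fr or len(set(fr)) != len(fr):
        raise ValueError("sweep fractions must be strictly increasing")
    n_total = cohort.n_images
    rows: list[SweepRow] = []
    for f in fr:
        reduced = exclude_worst_fraction(cohort, f)
        k = math.ceil(f * n_total)
        if k:
            ranked = sorted(cohort.iter_records(), key=lambda r: (-r.quality_pbad, r.image_id))
            cutoff = ranked[k - 1].quality_pbad
        else:
            cutoff = None
        try:
            results, summary = lambda_distribution(reduced, method, reference_sd, min_images)
            row = SweepRow(
                exclusion_fraction=f,
                pbad_cutoff=cutoff,
                n_images_retained=reduced.n_images,
                n_eyes_eligible=summary.n_eyes,
                lambda_min=summary.min,
                lambda_median=summary.median,
                lambda_max=summary.max,
            )
        except AnalysisError:
            logger.warning("sweep fraction %.2f leaves no eligible eyes; row flagged", f)
            row = SweepRow(
                exclusion_fraction=f,
                pbad_cutoff=cutoff,
                n_images_retained=reduced.n_images,
                n_eyes_eligible=0,
                lambda_min=float("nan"),
                lambda_median=float("nan"),
                lambda_max=float("nan"),
            )
        rows.append(row)
    return rows


def apply_quality_threshold(cohort: CohortTable, pbad_max: float) -> CohortTable:
    """Drop images with ``quality_pbad > pbad_max`` (the 'discard very bad
    images' rule; a threshold of 0.8 is the recommended gate)."""
    if not (0.0 <= pbad_max <= 1.0):
        raise ValueError(f"pbad_max must be in [0, 1], got {pbad_max}")
    return _rebuild(cohort, lambda r: r.quality_pbad <= pbad_max)


def lambda_quality_correlation(
    lambdas: Sequence[LambdaResult],
    scale: str = "probability",
) -> tuple[CorrelationResult, CorrelationResult]:
    """Correlate λ with the worst image quality per eye.

    ``scale`` is ``"probability"`` (worst P(bad) itself) or ``"logit"``
    (its logit, i.e. the quality model's raw output scale).  Returns
    (Pearson, Spearman).  As a runtime cross-check, Spearman is verified
    to be identical across the two scales, since the logistic link is
    monotone.
    """
    if scale not in {"probability", "logit"}:
        raise ValueError(f"unknown scale {scale!r}")
    if len(lambdas) < 3:
        raise AnalysisError(f"need >= 3 eyes, got {len(lambdas)}")
    lam = np.asarray([r.lambda_pct for r in lambdas], dtype=float)
    worst = np.asarray([r.worst_pbad for r in lambdas], dtype=float)
    keys = tuple((r.subject_id, r.eye) for r in lambdas)

    def _pair(x: np.ndarray) -> PairingTable:
        return PairingTable(rule="lambda_vs_quality", eye_keys=keys, value_a=lam, value_b=x)

    x = logit(worst) if scale == "logit" else worst
    pearson = correlation(_pair(x), "pearson")
    spearman = correlation(_pair(x), "spearman")

    other = worst if scale == "logit" else logit(worst)
    spearman_other = correlation(_pair(other), "spearman")
    if abs(spearman.estimate - spearman_other.estimate) > 1e-12:
        raise AssertionError(
            "Spearman differs across probability/logit scales; the link should be monotone"
        )
    return pearson, spearman
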