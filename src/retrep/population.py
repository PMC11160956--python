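"""Population-level repeatability metrics.

The population view of measurement noise treats each eye as one subject
and asks how well repeated measurements agree across the cohort:

* Pearson / Spearman correlation between paired measurements per eye —
  either the first and last image of each eye, or one random pairing per
  eye resampled many times with an empirical percentile interval;
* the intraclass correlation coefficient (ICC),

  .. math:: \\mathrm{ICC} = \\frac{\\sigma_b^2}{\\sigma_b^2 + \\sigma_w^2},

  where :math:`\\sigma_b` is the SD of the eyes' true trait values
  (estimated as the SD over eyes of the per-eye mean) and
  :math:`\\sigma_w` is the measurement-error SD (the pooled within-eye
  SD).  An *adjusted* ICC substitutes a between-eye SD estimated on a
  broader reference population for both occurrences of
  :math:`\\sigma_b`;
* between-method interchangeability: correlations and a Bland–Altman
  summary of per-eye mean values under a quality gate.

Pearson and Spearman estimates are computed by one shared row-wise
kernel so the single-pairing path and the resampling path use bit-for-bit
identical arithmetic; p-values use the usual t approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, DegenerateCorrelationError
from .io import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "VarianceDecomposition",
    "PairingTable",
    "BlandAltman",
    "InterchangeabilityResult",
    "first_last_pairing",
    "correlation",
    "random_pair_resampling",
    "variance_decomposition",
    "combined_reference_sd",
    "interchangeability",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with its two-sided p-value and, for
    resampled estimates, an empirical 2.5–97.5 percentile interval."""

    statistic: str  # "pearson" | "spearman"
    estimate: float
    p_value: float
    n_pairs: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
                raise ValueError("estimate outside its own empirical interval")

    def to_row(self) -> dict:
        return {
            "statistic": self.statistic,
            "estimate": self.estimate,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class VarianceDecomposition:
    """Between-eye / within-eye variance split and the ICC derived from it.

    ``sd_between`` is the sample SD over eyes of the per-eye mean trait;
    ``sd_within`` is the pooled within-eye sample SD.  ``icc`` and
    ``icc_adjusted`` are computed from these fields, so the ICC identity
    holds exactly by construction.
    """

    method: str
    sd_between: float
    sd_within: float
    n_eyes: int
    n_images: int
    reference_sd_between: float | None = None

    @property
    def icc(self) -> float:
        b2, w2 = self.sd_between**2, self.sd_within**2
        return b2 / (b2 + w2)

    @property
    def icc_adjusted(self) -> float | None:
        if self.reference_sd_between is None:
            return None
        b2 = self.reference_sd_between**2
        return b2 / (b2 + self.sd_within**2)

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "sd_between": self.sd_between,
            "sd_within": self.sd_within,
            "icc": self.icc,
            "icc_adjusted": self.icc_adjusted,
            "reference_sd_between": self.reference_sd_between,
            "n_eyes": self.n_eyes,
            "n_images": self.n_images,
        }


@dataclass(frozen=True)
class PairingTable:
    """One (value_a, value_b) pair per eye for a given method."""

    rule: str  # "first_last" | "first_next_visit" | "random"
    eye_keys: tuple[tuple[str, str], ...]
    value_a: np.ndarray
    value_b: np.ndarray
    n_skipped: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.eye_keys)


@dataclass(frozen=True)
class BlandAltman:
    """Mean difference and limits of agreement (mean ± 1.96 SD) of paired
    per-eye values from two methods."""

    mean_diff: float
    sd_diff: float
    n: int

    @property
    def loa_low(self) -> float:
        return self.mean_diff - 1.96 * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.mean_diff + 1.96 * self.sd_diff

    def to_row(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


@dataclass(frozen=True)
class InterchangeabilityResult:
    method_a: str
    method_b: str
    pbad_max: float
    pearson: CorrelationResult
    spearman: CorrelationResult
    bland_altman: BlandAltman
    n_eyes: int
    n_images_used: int


# ---------------------------------------------------------------- kernels

def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (reps, eyes) matrices."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / np.sqrt((Ac * Ac).sum(axis=1) * (Bc * Bc).sum(axis=1))


def _rank_rows(X: np.ndarray) -> np.ndarray:
    """Average ranks along rows (ties share their mean rank)."""
    return stats.rankdata(X, method="average", axis=1)


def _corr_p_value(r: float, n: int) -> float:
    """Two-sided p via the t approximation with n - 2 degrees of freedom."""
    if n < 3 or not np.isfinite(r):
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


# ------------------------------------------------------------- operations

def first_last_pairing(cohort: CohortTable, method: str) -> PairingTable:
    """Pair the earliest and latest usable image of each eye.

    Eyes with fewer than two usable images are skipped and counted in
    ``n_skipped``.  For a two-images-per-eye design this reduces to the
    baseline/follow-up pairing.
    """
    if method not in cohort.methods:
        raise AnalysisError(f"method {method!r} absent from cohort {cohort.name!r}")
    keys, a, b = [], [], []
    n_skipped = 0
    for eye in cohort.eyes:
        usable = eye.usable_records(method)
        if len(usable) < 2:
            n_skipped += 1
            continue
        keys.append(eye.key)
        a.append(usable[0].trait_values[method])
        b.append(usable[-1].trait_values[method])
    if n_skipped:
        logger.info(
            "first_last_pairing(%s, %s): skipped %d eyes with <2 usable images",
            cohort.name, method, n_skipped,
        )
    return PairingTable(
        rule="first_last",
        eye_keys=tuple(keys),
        value_a=np.asarray(a, dtype=float),
        value_b=np.asarray(b, dtype=float),
        n_skipped=n_skipped,
    )


def correlation(pairs: PairingTable, statistic: str) -> CorrelationResult:
    """Pearson or Spearman correlation of a pairing table.

    Spearman is the Pearson correlation of the average ranks of both
    variables.  Zero variance in either column raises
    :class:`DegenerateCorrelationError` naming the degenerate column.
    """
    if statistic not in {"pearson", "spearman"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    x = pairs.value_a[None, :]
    y = pairs.value_b[None, :]
    n = pairs.n_pairs
    if n < 3:
        raise AnalysisError(f"need >= 3 pairs, got {n}")
    if np.ptp(pairs.value_a) == 0:
        raise DegenerateCorrelationError("value_a")
    if np.ptp(pairs.value_b) == 0:
        raise DegenerateCorrelationError("value_b")
    if statistic == "spearman":
        x, y = _rank_rows(x), _rank_rows(y)
    r = float(_pearson_rows(x, y)[0])
    return CorrelationResult(statistic=statistic, estimate=r, p_value=_corr_p_value(r, n), n_pairs=n)


def random_pair_resampling(
    cohort: CohortTable,
    method: str,
    n_reps: int = 20000,
    seed: int = 0,
) -> tuple[CorrelationResult, CorrelationResult]:
    """Median correlation over random per-eye pairings.

    Each replicate draws, for every eligible eye, an unordered pair of
    two distinct images uniformly at random (kept in time order — the
    correlation is symmetric, this only fixes the arithmetic), computes
    Pearson and Spearman over eyes, and the function reports the median
    across replicates with the empirical 2.5/97.5 percentiles as the
    interval.  Deterministic given ``seed``.

    The percentile interval for Pearson can have inaccurate coverage, as
    resampling-based intervals for correlations are known to; treat it
    as descriptive.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in cohort.methods:
        raise AnalysisError(f"method {method!r} absent from cohort {cohort.name!r}")
    values = []
    n_excluded = 0
    for eye in cohort.eyes:
        v = np.asarray(eye.values(method), dtype=float)
        if v.size < 2:
            n_excluded += 1
            continue
        values.append(v)
    if n_excluded:
        logger.info(
            "random_pair_resampling(%s, %s): excluded %d eyes with <2 usable images",
            cohort.name, method, n_excluded,
        )
    n_eyes = len(values)
    if n_eyes == 0:
        raise AnalysisError("no eye has >= 2 usable images")
    if n_eyes < 3:
        raise AnalysisError(f"need >= 3 eligible eyes, got {n_eyes}")

    rng = np.random.default_rng(seed)
    A = np.empty((n_reps, n_eyes))
    B = np.empty((n_reps, n_eyes))
    for e, v in enumerate(values):
        n = v.size
        i = rng.integers(0, n, size=n_reps)
        j = rng.integers(0, n - 1, size=n_reps)
        j = j + (j >= i)  # j uniform over indices != i
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        A[:, e] = v[lo]
        B[:, e] = v[hi]

    results = []
    for statistic in ("pearson", "spearman"):
        if statistic == "spearman":
            r = _pearson_rows(_rank_rows(A), _rank_rows(B))
        else:
            r = _pearson_rows(A, B)
        est = float(np.median(r))
        lo_q, hi_q = np.quantile(r, [0.025, 0.975])
        results.append(
            CorrelationResult(
                statistic=statistic,
                estimate=est,
                p_value=_corr_p_value(est, n_eyes),
                n_pairs=n_eyes,
                ci_low=float(lo_q),
                ci_high=float(hi_q),
            )
        )
    return results[0], results[1]


def variance_decomposition(
    cohort: CohortTable,
    method: str,
    reference_sd_between: float | None = None,
) -> VarianceDecomposition:
    """Estimate the between-eye and within-eye SD and the ICC.

    The eyes' true values are estimated by the per-eye mean over all
    usable images; ``sd_between`` is the sample SD of those means.  The
    measurement-error SD ``sd_within`` pools per-eye sample variances
    weighted by their degrees of freedom (the one-way layout).  Eyes with
    a single usable image contribute to ``sd_between`` only.

    When ``reference_sd_between`` is supplied (a between-eye SD from a
    broader population), the adjusted ICC substitutes it for the cohort's
    own between-eye SD.
    """
    means, dofs, variances = [], [], []
    n_images = 0
    n_single = 0
    for eye in cohort.eyes:
        v = np.asarray(eye.values(method), dtype=float)
        if v.size == 0:
            continue
        n_images += v.size
        means.append(v.mean())
        if v.size >= 2:
            dofs.append(v.size - 1)
            variances.append(v.var(ddof=1))
        else:
            n_single += 1
    if len(means) < 2:
        raise AnalysisError(f"need >= 2 eyes with usable {method!r} values, got {len(means)}")
    if not dofs:
        raise AnalysisError("no eye has >= 2 usable images; within-eye SD inestimable")
    if n_single:
        logger.info(
            "variance_decomposition(%s, %s): %d single-image eyes in sd_between only",
            cohort.name, method, n_single,
        )
    sd_between = float(np.std(means, ddof=1))
    pooled_var = float(np.dot(dofs, variances) / np.sum(dofs))
    return VarianceDecomposition(
        method=method,
        sd_between=sd_between,
        sd_within=float(np.sqrt(pooled_var)),
        n_eyes=len(means),
        n_images=n_images,
        reference_sd_between=reference_sd_between,
    )


def combined_reference_sd(cohorts: Sequence[CohortTable], method: str) -> float:
    """Between-eye SD of per-eye means pooled over several cohorts.

    This is the reference spread used for the adjusted ICC and as the
    denominator of the individual-level noise statistic λ.
    """
    means = []
    for cohort in cohorts:
        for eye in cohort.eyes:
            v = eye.values(method)
            if v:
                means.append(float(np.mean(v)))
    if len(means) < 2:
        raise AnalysisError(f"need >= 2 eyes with {method!r} values across cohorts")
    return float(np.std(means, ddof=1))


def interchangeability(
    cohort: CohortTable,
    method_a: str,
    method_b: str,
    pbad_max: float = 0.8,
) -> InterchangeabilityResult:
    """Agreement between two measurement methods on per-eye means.

    Images with ``quality_pbad >= pbad_max`` are excluded; per-eye means
    over the surviving images (per method) reduce measurement noise.
    Returns Pearson and Spearman between the two mean vectors and a
    Bland–Altman summary of the differences (a − b).
    """
    for m in (method_a, method_b):
        if m not in cohort.methods:
            raise AnalysisError(f"method {m!r} absent from cohort {cohort.name!r}")
    keys, mean_a, mean_b = [], [], []
    n_used = 0
    for eye in cohort.eyes:
        surviving = [r for r in eye.records if r.quality_pbad < pbad_max]
        va = [r.trait_values[method_a] for r in surviving if method_a in r.trait_values]
        vb = [r.trait_values[method_b] for r in surviving if method_b in r.trait_values]
        if not va or not vb:
            continue
        keys.append(eye.key)
        mean_a.append(float(np.mean(va)))
        mean_b.append(float(np.mean(vb)))
        n_used += len(surviving)
    if len(keys) < 3:
        raise AnalysisError(f"only {len(keys)} eyes survive the quality gate; need >= 3")
    pairs = PairingTable(
        rule="per_eye_means",
        eye_keys=tuple(keys),
        value_a=np.asarray(mean_a),
        value_b=np.asarray(mean_b),
    )
    diff = pairs.value_a - pairs.value_b
    ba = BlandAltman(mean_diff=float(diff.mean()), sd_diff=float(diff.std(ddof=1)), n=diff.size)
    return InterchangeabilityResult(
        method_a=method_a,
        method_b=method_b,
        pbad_max=pbad_max,
        pearson=correlation(pairs, "pearson"),
        spearman=correlation(pairs, "spearman"),
        bland_altman=ba,
        n_eyes=len(keys),
        n_images_used=n_used,
    )
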