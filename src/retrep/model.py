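"""Model/Results interface over the repeatability analyses.

:class:`RepeatabilityModel` is constructed from a cohort (or a tidy
DataFrame) and one measurement method; :meth:`RepeatabilityModel.fit`
runs the full population- and individual-level analysis and returns a
:class:`RepeatabilityResults` carrying the estimates, the resampling
intervals, the λ table and a ``summary()`` in the familiar
fitted-model style.  Quality-robustness analyses (exclusion sweep,
λ-vs-quality correlation) and plots hang off the results object.

Example
-------
>>> from retrep import simulate
>>> from retrep.model import RepeatabilityModel
>>> cohort, _ = simulate.generate_cohort(simulate.preset("caledonia-like", seed=7))
>>> res = RepeatabilityModel(cohort, "DART").fit(n_reps=2000, seed=7)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import AnalysisError
from .individual import LambdaResult, LambdaSummary, lambda_distribution
from .io import CohortTable, TableSchema
from .population import (
    CorrelationResult,
    InterchangeabilityResult,
    VarianceDecomposition,
    combined_reference_sd,
    correlation,
    first_last_pairing,
    interchangeability,
    random_pair_resampling,
    variance_decomposition,
)
from .quality import (
    DEFAULT_SWEEP_FRACTIONS,
    SweepRow,
    exclusion_sweep,
    lambda_quality_correlation,
)

__all__ = ["RepeatabilityModel", "RepeatabilityResults"]


class RepeatabilityModel:
    """Repeatability of one measurement method over a cohort of eyes.

    Parameters
    ----------
    cohort
        The measurement table, grouped into eye series.
    method
        Name of the trait column to analyse.
    reference_sd
        Between-eyes SD used as the λ denominator and for the adjusted
        ICC.  ``None`` estimates it from the analysis cohort pooled with
        ``reference_cohorts`` (the recommended broader reference).
    reference_cohorts
        Additional cohorts pooled into the reference SD estimate.
    """

    def __init__(
        self,
        cohort: CohortTable,
        method: str,
        reference_sd: Optional[float] = None,
        reference_cohorts: Sequence[CohortTable] = (),
    ):
        if method not in cohort.methods:
            raise AnalysisError(f"method {method!r} absent from cohort {cohort.name!r}")
        self.cohort = cohort
        self.method = method
        self._reference_sd = reference_sd
        self.reference_cohorts = list(reference_cohorts)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        method: str,
        name: str = "cohort",
        schema: Optional[TableSchema] = None,
        **kwargs,
    ) -> "RepeatabilityModel":
        """Build from a tidy one-row-per-image DataFrame."""
        import io as _io

        from .io import read_measurement_table

        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        # reuse the validated reading path on an in-memory table
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            p = Path(tmp) / f"{name}.csv"
            p.write_text(buf.getvalue())
            cohort = read_measurement_table(p, schema=schema, name=name)
        return cls(cohort, method, **kwargs)

    @property
    def reference_sd(self) -> float:
        if self._reference_sd is not None:
            return self._reference_sd
        pool = [self.cohort, *self.reference_cohorts]
        return combined_reference_sd(pool, self.method)

    def fit(self, n_reps: int = 20000, seed: int = 0) -> "RepeatabilityResults":
        """Run the full analysis.

        ``n_reps`` controls the random-pair resampling (skipped when no
        eye has more than two usable images, where it degenerates to the
        first–last pairing); ``seed`` makes the fit deterministic.
        """
        ref_sd = self.reference_sd
        vd = variance_decomposition(self.cohort, self.method, reference_sd_between=ref_sd)
        pairs = first_last_pairing(self.cohort, self.method)
        fl_pearson = correlation(pairs, "pearson")
        fl_spearman = correlation(pairs, "spearman")
        max_usable = max(
            (len(e.usable_records(self.method)) for e in self.cohort.eyes), default=0
        )
        rp_pearson = rp_spearman = None
        if max_usable > 2:
            rp_pearson, rp_spearman = random_pair_resampling(
                self.cohort, self.method, n_reps=n_reps, seed=seed
            )
        lambdas, lam_summary = lambda_distribution(self.cohort, self.method, ref_sd)
        return RepeatabilityResults(
            model=self,
            reference_sd=ref_sd,
            variance=vd,
            pearson_first_last=fl_pearson,
            spearman_first_last=fl_spearman,
            pearson_random_pairs=rp_pearson,
            spearman_random_pairs=rp_spearman,
            lambdas=lambdas,
            lambda_summary=lam_summary,
            n_reps=n_reps,
            seed=seed,
        )


@dataclass
class RepeatabilityResults:
    """Fitted repeatability estimates for one cohort and method."""

    model: RepeatabilityModel
    reference_sd: float
    variance: VarianceDecomposition
    pearson_first_last: CorrelationResult
    spearman_first_last: CorrelationResult
    pearson_random_pairs: Optional[CorrelationResult]
    spearman_random_pairs: Optional[CorrelationResult]
    lambdas: list[LambdaResult] = field(repr=False)
    lambda_summary: LambdaSummary = None
    n_reps: int = 20000
    seed: int = 0

    # -- derived quantities -------------------------------------------

    @property
    def icc(self) -> float:
        return self.variance.icc

    @property
    def icc_adjusted(self) -> Optional[float]:
        return self.variance.icc_adjusted

    def lambda_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.lambdas])

    def sweep(
        self,
        fractions: Sequence[float] = DEFAULT_SWEEP_FRACTIONS,
        min_images: int = 2,
    ) -> list[SweepRow]:
        """Quality-exclusion sweep with the fitted reference SD held fixed."""
        return exclusion_sweep(
            self.model.cohort, self.model.method, self.reference_sd,
            fractions=fractions, min_images=min_images,
        )

    def quality_correlation(self, scale: str = "probability"):
        """(Pearson, Spearman) between λ and worst P(bad) per eye."""
        return lambda_quality_correlation(self.lambdas, scale=scale)

    def interchangeability_with(
        self, other_method: str, pbad_max: float = 0.8
    ) -> InterchangeabilityResult:
        return interchangeability(self.model.cohort, self.model.method, other_method, pbad_max)

    # -- presentation --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "cohort": self.model.cohort.name,
            "method": self.model.method,
            "n_eyes": self.variance.n_eyes,
            "n_images": self.variance.n_images,
            "reference_sd": self.reference_sd,
            "sd_between": self.variance.sd_between,
            "sd_within": self.variance.sd_within,
            "icc": self.icc,
            "icc_adjusted": self.icc_adjusted,
            "pearson_first_last": self.pearson_first_last.estimate,
            "spearman_first_last": self.spearman_first_last.estimate,
            "lambda_median_pct": self.lambda_summary.median,
            "lambda_q3_pct": self.lambda_summary.q3,
            "lambda_max_pct": self.lambda_summary.max,
        }
        if self.pearson_random_pairs is not None:
            d["pearson_random_pairs"] = self.pearson_random_pairs.estimate
            d["pearson_random_pairs_ci"] = (
                self.pearson_random_pairs.ci_low,
                self.pearson_random_pairs.ci_high,
            )
            d["spearman_random_pairs"] = self.spearman_random_pairs.estimate
            d["spearman_random_pairs_ci"] = (
                self.spearman_random_pairs.ci_low,
                self.spearman_random_pairs.ci_high,
            )
        return d

    def summary(self) -> str:
        """Human-readable report in the fitted-model style."""
        v = self.variance
        lines = [
            "Repeatability Results",
            "=" * 58,
            f"Cohort:            {self.model.cohort.name}",
            f"Method:            {self.model.method}",
            f"Eyes / images:     {v.n_eyes} / {v.n_images}",
            f"Reference SD:      {self.reference_sd:.6g}",
            "-" * 58,
            f"SD between eyes:   {v.sd_between:.6g}",
            f"SD within eyes:    {v.sd_within:.6g}",
            f"ICC:               {v.icc:.4f}",
        ]
        if v.icc_adjusted is not None:
            lines.append(f"Adjusted ICC:      {v.icc_adjusted:.4f}")
        lines += [
            "-" * 58,
            "Correlation (first/last image per eye):",
            f"  Pearson  {self.pearson_first_last.estimate:.4f}"
            f"  (p={self.pearson_first_last.p_value:.2g})",
            f"  Spearman {self.spearman_first_last.estimate:.4f}"
            f"  (p={self.spearman_first_last.p_value:.2g})",
        ]
        if self.pearson_random_pairs is not None:
            rp, rs = self.pearson_random_pairs, self.spearman_random_pairs
            lines += [
                f"Correlation ({self.n_reps} random pairs per eye, median [95% emp.]):",
                f"  Pearson  {rp.estimate:.4f}  [{rp.ci_low:.4f}, {rp.ci_high:.4f}]",
                f"  Spearman {rs.estimate:.4f}  [{rs.ci_low:.4f}, {rs.ci_high:.4f}]",
                "  (the Pearson interval may have inaccurate coverage)",
            ]
        s = self.lambda_summary
        lines += [
            "-" * 58,
            f"Individual-level noise lambda (% of reference SD), {s.n_eyes} eyes:",
            f"  min {s.min:.2f}   q1 {s.q1:.2f}   median {s.median:.2f}"
            f"   q3 {s.q3:.2f}   max {s.max:.2f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------

    def plot_lambda(self, ax=None):
        from .plotting import plot_lambda_box

        return plot_lambda_box({self.model.cohort.name: self.lambdas}, ax=ax)

    def plot_sweep(self, rows: Optional[list[SweepRow]] = None, ax=None):
        from .plotting import plot_sweep

        return plot_sweep(rows if rows is not None else self.sweep(), ax=ax)

    def plot_lambda_vs_quality(self, scale: str = "probability", ax=None):
        from .plotting import plot_lambda_vs_quality

        return plot_lambda_vs_quality(self.lambdas, scale=scale, ax=ax)
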