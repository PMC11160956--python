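"""End-to-end orchestration: read cohorts, run every analysis, write a
report bundle (CSV tables, JSON summary, plots, manifest).

Exclusion accounting is the analysis' central methodological concern,
so every stage logs how many eyes/images it dropped, and the manifest
records the seed and a content hash of every output file.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .errors import RetrepError
from .io import CohortTable, read_measurement_table, write_json_summary, write_results
from .model import RepeatabilityModel
from .population import combined_reference_sd, interchangeability
from .quality import DEFAULT_SWEEP_FRACTIONS
from .simulate import generate_cohort, preset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "demo"]


class RunConfig(BaseModel):
    """Configuration of one full analysis run."""

    input_paths: list[Path] = Field(default_factory=list)
    methods: list[str] = Field(default_factory=list)  # empty: analyse all found
    n_reps: int = 20000
    seed: int = 0
    reference_sd: Optional[float] = None  # None = pooled across all inputs
    sweep_fractions: list[float] = Field(default_factory=lambda: list(DEFAULT_SWEEP_FRACTIONS))
    min_images: int = 2
    pbad_max: float = 0.8
    out_dir: Path = Path("retrep_out")
    make_plots: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)


def run_full_analysis(
    config: RunConfig, cohorts: Optional[Sequence[CohortTable]] = None
) -> dict:
    """Run the full pipeline and write the report bundle.

    ``cohorts`` may be passed directly (e.g. freshly simulated); otherwise
    they are read from ``config.input_paths``.  Returns the JSON summary
    as a dict.  Deterministic given the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohorts is None:
        _stage("read inputs")
        cohorts = [read_measurement_table(p) for p in config.input_paths]
    if not cohorts:
        raise RetrepError("no input cohorts")

    methods = config.methods or sorted({m for c in cohorts for m in c.methods})
    summary: dict = {
        "tool": "retrep",
        "version": __version__,
        "seed": config.seed,
        "cohorts": {c.name: {"n_eyes": c.n_eyes, "n_images": c.n_images} for c in cohorts},
        "methods": methods,
        "results": {},
    }
    outputs: list[Path] = []

    for cohort in cohorts:
        for m in methods:
            if m not in cohort.methods:
                raise RetrepError(
                    f"stage reference: method {m!r} not found in cohort {cohort.name!r}"
                )

    reference = {}
    _stage("reference SD (pooled across cohorts)")
    for m in methods:
        reference[m] = (
            config.reference_sd
            if config.reference_sd is not None
            else combined_reference_sd(cohorts, m)
        )

    pop_rows = []
    for cohort in cohorts:
        for m in methods:
            if m not in cohort.methods:
                raise RetrepError(f"stage population[{cohort.name}]: method {m!r} not found")
            _stage(f"population + lambda: {cohort.name} / {m}")
            model = RepeatabilityModel(cohort, m, reference_sd=reference[m])
            res = model.fit(n_reps=config.n_reps, seed=config.seed)
            block = res.to_dict()
            pop_rows.append(block)
            key = f"{cohort.name}/{m}"
            summary["results"][key] = block

            lam_path = out / f"lambda_{cohort.name}_{m}.csv"
            write_results(res.lambdas, lam_path)
            outputs.append(lam_path)

            _stage(f"exclusion sweep: {cohort.name} / {m}")
            sweep_rows = res.sweep(config.sweep_fractions, config.min_images)
            sweep_path = out / f"sweep_{cohort.name}_{m}.csv"
            write_results(sweep_rows, sweep_path)
            outputs.append(sweep_path)
            summary["results"][key]["sweep_max_at_0"] = sweep_rows[0].lambda_max
            summary["results"][key]["sweep_max_at_last"] = sweep_rows[-1].lambda_max

            _stage(f"lambda-quality correlation: {cohort.name} / {m}")
            qc = {}
            for scale in ("probability", "logit"):
                pe, sp = res.quality_correlation(scale)
                qc[scale] = {"pearson": pe.estimate, "spearman": sp.estimate}
            summary["results"][key]["lambda_quality"] = qc

            if config.make_plots:
                _plots(out, cohort.name, m, res, sweep_rows, outputs)

        if len(methods) >= 2:
            a, b = methods[0], methods[1]
            _stage(f"interchangeability: {cohort.name} {a} vs {b}")
            inter = interchangeability(cohort, a, b, pbad_max=config.pbad_max)
            summary["results"][f"{cohort.name}/interchangeability"] = {
                "method_a": a,
                "method_b": b,
                "pearson": inter.pearson.estimate,
                "spearman": inter.spearman.estimate,
                "mean_diff": inter.bland_altman.mean_diff,
                "loa_low": inter.bland_altman.loa_low,
                "loa_high": inter.bland_altman.loa_high,
                "n_eyes": inter.n_eyes,
            }

    pop_path = out / "population_metrics.csv"
    write_results(pd.DataFrame(pop_rows), pop_path)
    outputs.append(pop_path)

    summary_path = out / "summary.json"
    write_json_summary(summary, summary_path)
    outputs.append(summary_path)

    manifest = {
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "files": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    write_json_summary(manifest, out / "manifest.json")
    return summary


def _plots(out: Path, cohort: str, method: str, res, sweep_rows, outputs: list[Path]) -> None:
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    for name, draw in (
        ("lambda_box", lambda ax: res.plot_lambda(ax=ax)),
        ("sweep", lambda ax: res.plot_sweep(sweep_rows, ax=ax)),
        ("lambda_vs_quality", lambda ax: res.plot_lambda_vs_quality(ax=ax)),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        draw(ax)
        path = out / f"plot_{name}_{cohort}_{method}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)


def demo(seed: int = 0, out_dir: str | Path = "retrep_demo", n_reps: int = 20000) -> dict:
    """Generate both design presets, write them to CSV and run the full
    analysis on the simulated cohorts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = []
    for name in ("caledonia-like", "grape-like"):
        cohort, truth = generate_cohort(preset(name, seed=seed))
        cohorts.append(cohort)
        write_results(cohort.to_dataframe(), out / f"cohort_{name}.csv")
        write_results(truth, out / f"truth_{name}.csv")
    config = RunConfig(seed=seed, n_reps=n_reps, out_dir=out)
    return run_full_analysis(config, cohorts=cohorts)
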