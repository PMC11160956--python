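"""Synthetic cohort generator with known ground truth.

The generator produces per-image measurement tables with the statistical
structure the repeatability analysis assumes:

* each eye has a latent true trait value drawn around the population
  mean with a between-eye SD;
* each image carries a quality score P(bad) ~ Beta(α, β);
* within-eye measurement noise grows with poor quality through a
  logit-linear link: the per-image noise SD is
  ``sigma_within_base * (1 + noise_logit_slope * max(0, logit(pbad)))``,
  so all images better than P(bad) = 0.5 share a common noise floor;
* images with P(bad) above a threshold are, with some probability,
  contaminated by an additional gross error — an additive draw of SD
  ``outlier_scale * sigma_between`` — emulating the badly illuminated
  frames that dominate an eye's within-eye SD in real data;
* in longitudinal designs the true trait drifts between visits
  (visit-to-visit steps of SD ``drift_sd``); images taken on the same
  visit share the drifted truth.

Several measurement methods can be generated for the same cohort.  They
share the eyes' latent truth (standardised), the visit-drift trajectory
and the outlier flags, but have independent noise and their own scales —
mirroring two tools measuring the same quantity with different
calibrations and different noise levels.

Two presets mirror the study designs the analysis is aimed at:
``"caledonia-like"`` (26 subjects, 39 eyes, 5–15 same-day images per eye
totalling 377, no drift, mostly good quality) and ``"grape-like"``
(106 subjects, 196 eyes, exactly one baseline and one follow-up image
each, 392 images, between-visit drift, more mixed quality).

Everything is reproducible from the config's ``seed``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .io import CohortTable, ImageRecord

__all__ = ["MethodParams", "GeneratorConfig", "generate_cohort", "preset", "PRESET_NAMES"]

PRESET_NAMES = ("caledonia-like", "grape-like")


class MethodParams(BaseModel):
    """Scales of one measurement method (trait units are dimensionless)."""

    mu_trait: float = 1.5
    sigma_between: float = Field(ge=0.0)
    sigma_within_base: float = Field(ge=0.0)
    drift_sd: float = Field(default=0.0, ge=0.0)


class GeneratorConfig(BaseModel):
    """Full parameterisation of the synthetic data-generating process.

    The scalar fields ``mu_trait`` / ``sigma_between`` /
    ``sigma_within_base`` / ``drift_sd`` describe a single method named
    ``"trait"``; supplying ``methods`` instead generates several methods
    that share latent structure (see module docstring).
    """

    n_subjects: int = Field(ge=1)
    eyes_per_subject: int = Field(default=2, ge=1, le=2)
    n_eyes: Optional[int] = Field(default=None, ge=1)
    images_per_eye: int | tuple[int, int] = 2
    total_images: Optional[int] = Field(default=None, ge=1)

    mu_trait: float = 1.5
    sigma_between: Optional[float] = Field(default=None, ge=0.0)
    sigma_within_base: Optional[float] = Field(default=None, ge=0.0)
    drift_sd: float = Field(default=0.0, ge=0.0)
    methods: Optional[dict[str, MethodParams]] = None

    quality_alpha: float = Field(default=1.0, gt=0.0)
    quality_beta: float = Field(default=4.0, gt=0.0)
    noise_logit_slope: float = Field(default=0.0, ge=0.0)
    outlier_pbad_threshold: float = Field(default=0.8, ge=0.0, le=1.0)
    outlier_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    outlier_scale: float = Field(default=0.0, ge=0.0)

    n_visits: int | tuple[int, int] = 1
    visit_interval_days: float = Field(default=30.0, gt=0.0)
    start_date: str = "2022-01-03"
    seed: int = 0
    name: str = "synthetic"

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.methods is None:
            if self.sigma_between is None or self.sigma_within_base is None:
                raise ValueError("either methods or sigma_between + sigma_within_base required")
        if isinstance(self.images_per_eye, tuple):
            lo, hi = self.images_per_eye
            if not (1 <= lo <= hi):
                raise ValueError("images_per_eye range must satisfy 1 <= min <= max")
        elif self.images_per_eye < 1:
            raise ValueError("images_per_eye must be >= 1")
        if isinstance(self.n_visits, tuple):
            lo, hi = self.n_visits
            if not (1 <= lo <= hi):
                raise ValueError("n_visits range must satisfy 1 <= min <= max")
        n_eyes = self.resolved_n_eyes()
        if not (self.n_subjects <= n_eyes <= self.n_subjects * self.eyes_per_subject):
            raise ValueError(
                f"n_eyes={n_eyes} incompatible with {self.n_subjects} subjects x "
                f"{self.eyes_per_subject} eyes"
            )
        return self

    def resolved_n_eyes(self) -> int:
        return self.n_eyes if self.n_eyes is not None else self.n_subjects * self.eyes_per_subject

    def resolved_methods(self) -> dict[str, MethodParams]:
        if self.methods is not None:
            return self.methods
        return {
            "trait": MethodParams(
                mu_trait=self.mu_trait,
                sigma_between=self.sigma_between,
                sigma_within_base=self.sigma_within_base,
                drift_sd=self.drift_sd,
            )
        }


def _eye_layout(config: GeneratorConfig) -> list[tuple[str, str]]:
    """(subject_id, eye) keys: earlier subjects get both eyes until the
    eye budget is spent."""
    n_eyes = config.resolved_n_eyes()
    keys: list[tuple[str, str]] = []
    n_double = n_eyes - config.n_subjects if config.eyes_per_subject == 2 else 0
    for s in range(config.n_subjects):
        sid = f"S{s + 1:03d}"
        keys.append((sid, "right"))
        if s < n_double:
            keys.append((sid, "left"))
    return keys


def _image_counts(config: GeneratorConfig, n_eyes: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.images_per_eye, tuple):
        lo, hi = config.images_per_eye
        counts = rng.integers(lo, hi + 1, size=n_eyes)
    else:
        lo = hi = config.images_per_eye
        counts = np.full(n_eyes, lo, dtype=np.int64)
    if config.total_images is not None:
        target = config.total_images
        if not (n_eyes * lo <= target <= n_eyes * hi):
            raise ValueError(
                f"total_images={target} unreachable with {n_eyes} eyes in [{lo}, {hi}]"
            )
        # nudge random eyes within bounds until the total matches
        while counts.sum() != target:
            i = rng.integers(n_eyes)
            if counts.sum() < target and counts[i] < hi:
                counts[i] += 1
            elif counts.sum() > target and counts[i] > lo:
                counts[i] -= 1
    return counts


def _visit_assignment(n_images: int, n_visits: int, rng: np.random.Generator) -> np.ndarray:
    """Visit index per image; every visit gets at least one image when
    possible, the rest are spread at random."""
    if n_visits <= 1 or n_images <= 1:
        return np.zeros(n_images, dtype=np.int64)
    base = np.arange(min(n_visits, n_images))
    extra = rng.integers(0, n_visits, size=max(0, n_images - n_visits))
    return np.sort(np.concatenate([base, extra]))[:n_images]


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Generate a cohort and its image-level ground-truth table.

    The truth table has one row per image with the eye's (drifted) true
    trait value, the per-image noise SD and the outlier flag for each
    method, enabling recovery tests against known parameters.
    """
    rng = np.random.default_rng(config.seed)
    methods = config.resolved_methods()
    keys = _eye_layout(config)
    n_eyes = len(keys)
    counts = _image_counts(config, n_eyes, rng)
    start = pd.Timestamp(config.start_date)

    records: list[ImageRecord] = []
    truth_rows: list[dict] = []
    for e, ((sid, eye), n_img) in enumerate(zip(keys, counts)):
        z_eye = rng.normal()  # latent truth, shared across methods
        if isinstance(config.n_visits, tuple):
            v_lo, v_hi = config.n_visits
            n_visits = int(rng.integers(v_lo, v_hi + 1))
        else:
            n_visits = config.n_visits
        visits = _visit_assignment(n_img, n_visits, rng)
        drift_z = np.concatenate([[0.0], np.cumsum(rng.normal(size=max(n_visits - 1, 0)))])
        pbad = rng.beta(config.quality_alpha, config.quality_beta, size=n_img)
        with np.errstate(divide="ignore"):
            pos_logit = np.maximum(0.0, np.log(pbad / (1.0 - pbad)))
        noise_factor = 1.0 + config.noise_logit_slope * pos_logit
        is_outlier = (pbad > config.outlier_pbad_threshold) & (rng.random(n_img) < config.outlier_prob)

        noise_z = {m: rng.normal(size=n_img) for m in methods}
        outlier_z = {m: rng.normal(size=n_img) for m in methods}

        subject_day_offset = float(rng.integers(0, 200))
        for k in range(n_img):
            ts = (
                start
                + pd.Timedelta(days=subject_day_offset + visits[k] * config.visit_interval_days)
                + pd.Timedelta(minutes=3 * k)
            )
            image_id = f"{sid}_{eye[0].upper()}_{k + 1:02d}"
            traits: dict[str, float] = {}
            row = {
                "subject_id": sid,
                "eye": eye,
                "image_id": image_id,
                "visit": int(visits[k]),
                "quality_pbad": float(pbad[k]),
                "outlier": bool(is_outlier[k]),
            }
            for m, p in methods.items():
                true_eye = p.mu_trait + p.sigma_between * z_eye
                true_here = true_eye + p.drift_sd * drift_z[visits[k]]
                sd_here = p.sigma_within_base * noise_factor[k]
                value = true_here + sd_here * noise_z[m][k]
                if is_outlier[k]:
                    value += config.outlier_scale * p.sigma_between * outlier_z[m][k]
                # trait values are physically positive; a gross error that
                # undershoots zero is floored and stays a gross outlier
                traits[m] = float(max(value, 1e-3))
                row[f"true_{m}"] = float(true_here)
                row[f"true_eye_{m}"] = float(true_eye)
                row[f"noise_sd_{m}"] = float(sd_here)
            truth_rows.append(row)
            records.append(
                ImageRecord(
                    subject_id=sid,
                    eye=eye,
                    image_id=image_id,
                    acquired_at=ts,
                    trait_values=traits,
                    quality_pbad=float(pbad[k]),
                )
            )
    cohort = CohortTable.from_records(config.name, records)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def preset(
    name: str,
    method_sds: Optional[dict[str, float]] = None,
    seed: int = 0,
    **overrides,
) -> GeneratorConfig:
    """Config reproducing one of the two study-design shapes.

    ``method_sds`` overrides the between-eye SD per method; any other
    config field can be overridden by keyword.  Defaults carry the
    designs' published shapes and eye-level trait SDs for the two
    fractal-dimension tools (DART, AutoMorph).
    """
    if name == "caledonia-like":
        cfg = dict(
            n_subjects=26,
            eyes_per_subject=2,
            n_eyes=39,
            images_per_eye=(5, 15),
            total_images=377,
            methods={
                "DART": MethodParams(
                    mu_trait=1.75, sigma_between=0.00733, sigma_within_base=0.0010
                ),
                "AutoMorph": MethodParams(
                    mu_trait=1.58, sigma_between=0.02421, sigma_within_base=0.0090
                ),
            },
            quality_alpha=0.7,
            quality_beta=2.2,
            noise_logit_slope=2.0,
            outlier_pbad_threshold=0.8,
            outlier_prob=0.95,
            outlier_scale=8.0,
            n_visits=(1, 2),
            visit_interval_days=35.0,
            name="caledonia-like",
        )
    elif name == "grape-like":
        cfg = dict(
            n_subjects=106,
            eyes_per_subject=2,
            n_eyes=196,
            images_per_eye=2,
            total_images=392,
            methods={
                "DART": MethodParams(
                    mu_trait=1.75, sigma_between=0.03653, sigma_within_base=0.0040,
                    drift_sd=0.012,
                ),
                "AutoMorph": MethodParams(
                    mu_trait=1.58, sigma_between=0.08926, sigma_within_base=0.0180,
                    drift_sd=0.030,
                ),
            },
            quality_alpha=0.8,
            quality_beta=2.0,
            noise_logit_slope=2.0,
            outlier_pbad_threshold=0.8,
            outlier_prob=0.95,
            outlier_scale=8.0,
            n_visits=2,
            visit_interval_days=550.0,
            name="grape-like",
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg["seed"] = seed
    cfg.update(overrides)
    config = GeneratorConfig(**cfg)
    if method_sds:
        methods = dict(config.methods)
        for m, sd in method_sds.items():
            if m not in methods:
                raise ValueError(f"method {m!r} not in preset {name!r}")
            methods[m] = methods[m].model_copy(update={"sigma_between": sd})
        config = config.model_copy(update={"methods": methods})
    return config
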