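"""Population-level metrics against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retrep.errors import AnalysisError, DegenerateCorrelationError
from retrep.population import (
    PairingTable,
    combined_reference_sd,
    correlation,
    first_last_pairing,
    interchangeability,
    random_pair_resampling,
    variance_decomposition,
)
from retrep.simulate import generate_cohort, preset

from conftest import make_cohort


# ---------------------------------------------------------------- oracles

def pearson_oracle(x, y):
    """Textbook sum formula, written independently of the implementation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def rank_oracle(x):
    """Average ranks by explicit enumeration."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(rank_oracle(x), rank_oracle(y))


def decomposition_oracle(groups):
    """Two-pass between/within split by explicit loops."""
    means = [sum(g) / len(g) for g in groups]
    grand = sum(means) / len(means)
    sd_between = math.sqrt(sum((m - grand) ** 2 for m in means) / (len(means) - 1))
    num = den = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        m = sum(g) / len(g)
        num += sum((v - m) ** 2 for v in g)
        den += len(g) - 1
    sd_within = math.sqrt(num / den)
    return sd_between, sd_within


def _pairs(xs, ys):
    return PairingTable(
        rule="test",
        eye_keys=tuple(("S", str(i)) for i in range(len(xs))),
        value_a=np.asarray(xs, dtype=float),
        value_b=np.asarray(ys, dtype=float),
    )


# ----------------------------------------------------------------- pairing

class TestFirstLastPairing:
    def test_pairs_earliest_and_latest(self):
        cohort = make_cohort({("A", "right"): [1.1, 1.2, 1.3, 1.4, 1.5]})
        p = first_last_pairing(cohort, "FD")
        assert p.value_a.tolist() == [1.1] and p.value_b.tolist() == [1.5]

    def test_single_image_eye_skipped_and_counted(self):
        cohort = make_cohort({("A", "right"): [1.1], ("B", "right"): [1.2, 1.3]})
        p = first_last_pairing(cohort, "FD")
        assert p.n_pairs == 1 and p.n_skipped == 1

    def test_missing_method_raises(self):
        cohort = make_cohort({("A", "right"): [1.1, 1.2]})
        with pytest.raises(AnalysisError, match="absent"):
            first_last_pairing(cohort, "nope")

    def test_two_image_design_equals_visit_pairing(self):
        cohort, _ = generate_cohort(preset("grape-like", seed=1))
        p = first_last_pairing(cohort, "DART")
        assert p.n_pairs == 196
        for (sid, eye), a, b in zip(p.eye_keys, p.value_a, p.value_b):
            series = next(e for e in cohort.eyes if e.key == (sid, eye))
            assert (a, b) == (
                series.records[0].trait_values["DART"],
                series.records[1].trait_values["DART"],
            )


# ------------------------------------------------------------- correlation

class TestCorrelation:
    def test_perfect_linearity(self):
        r = correlation(_pairs([1, 2, 3], [2, 4, 6]), "pearson")
        assert r.estimate == pytest.approx(1.0, abs=1e-15)

    def test_monotone_nonlinear(self):
        pairs = _pairs([1, 2, 3, 4], [1, 8, 27, 64])
        assert correlation(pairs, "spearman").estimate == pytest.approx(1.0, abs=1e-15)
        assert correlation(pairs, "pearson").estimate < 1.0

    def test_matches_textbook_oracle_on_bivariate_normal(self):
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=50)
        pairs = _pairs(z[:, 0], z[:, 1])
        for stat, oracle in (("pearson", pearson_oracle), ("spearman", spearman_oracle)):
            got = correlation(pairs, stat).estimate
            assert got == pytest.approx(oracle(z[:, 0].tolist(), z[:, 1].tolist()), abs=1e-12)

    def test_zero_variance_names_degenerate_column(self):
        with pytest.raises(DegenerateCorrelationError, match="value_b"):
            correlation(_pairs([1, 2, 3], [5, 5, 5]), "pearson")

    def test_too_few_pairs(self):
        with pytest.raises(AnalysisError, match=">= 3"):
            correlation(_pairs([1, 2], [3, 4]), "pearson")

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-500, max_value=500), min_size=4, max_size=12, unique=True),
        st.floats(min_value=0.1, max_value=3.0),
    )
    def test_spearman_invariant_under_increasing_transform(self, xs, power):
        # integer-valued points: the signed power map stays injective
        ys = list(range(len(xs)))
        base = correlation(_pairs(xs, ys), "spearman").estimate
        transformed = correlation(
            _pairs([math.copysign(abs(x) ** power, x) for x in xs], ys), "spearman"
        ).estimate
        assert transformed == pytest.approx(base, abs=1e-12)


# -------------------------------------------------------------- resampling

class TestRandomPairResampling:
    def test_noiseless_cohort_gives_perfect_median_and_zero_width(self):
        cohort = make_cohort(
            {("A", "r"): [1.1] * 4, ("B", "r"): [1.2] * 3, ("C", "r"): [1.3] * 5}
        )
        pe, sp = random_pair_resampling(cohort, "FD", n_reps=200, seed=0)
        for r in (pe, sp):
            assert r.estimate == pytest.approx(1.0, abs=1e-15)
            assert r.ci_high - r.ci_low == 0.0

    def test_two_images_per_eye_reproduces_first_last_exactly(self):
        cohort = make_cohort(
            {("A", "r"): [1.1, 1.15], ("B", "r"): [1.3, 1.25], ("C", "r"): [1.2, 1.22],
             ("D", "r"): [1.4, 1.38]}
        )
        pe, sp = random_pair_resampling(cohort, "FD", n_reps=500, seed=7)
        fl = first_last_pairing(cohort, "FD")
        assert pe.estimate == correlation(fl, "pearson").estimate  # bit-for-bit
        assert sp.estimate == correlation(fl, "spearman").estimate
        assert pe.ci_high == pe.ci_low

    def test_deterministic_given_seed(self):
        cohort, _ = generate_cohort(preset("caledonia-like", seed=3))
        a = random_pair_resampling(cohort, "DART", n_reps=300, seed=5)
        b = random_pair_resampling(cohort, "DART", n_reps=300, seed=5)
        assert a[0].estimate == b[0].estimate and a[1].ci_low == b[1].ci_low

    def test_all_eyes_too_small_raises(self):
        cohort = make_cohort({("A", "r"): [1.1], ("B", "r"): [1.2]})
        with pytest.raises(AnalysisError):
            random_pair_resampling(cohort, "FD", n_reps=10, seed=0)


# ----------------------------------------------------- variance decomposition

class TestVarianceDecomposition:
    def test_matches_brute_force_oracle_on_toy_table(self, toy_cohort):
        groups = [eye.values("FD") for eye in toy_cohort.eyes]
        sd_b, sd_w = decomposition_oracle(groups)
        vd = variance_decomposition(toy_cohort, "FD")
        assert vd.sd_between == pytest.approx(sd_b, abs=1e-12)
        assert vd.sd_within == pytest.approx(sd_w, abs=1e-12)
        icc_oracle = sd_b**2 / (sd_b**2 + sd_w**2)
        assert vd.icc == pytest.approx(icc_oracle, abs=1e-12)

    def test_noiseless_cohort_has_icc_one(self):
        cohort = make_cohort({("A", "r"): [1.1] * 3, ("B", "r"): [1.2] * 3, ("C", "r"): [1.3] * 2})
        assert variance_decomposition(cohort, "FD").icc == 1.0

    def test_two_eye_worked_example(self):
        cohort = make_cohort({("A", "r"): [0.9, 1.1], ("B", "r"): [1.9, 2.1]})
        vd = variance_decomposition(cohort, "FD")
        sd_b, sd_w = decomposition_oracle([[0.9, 1.1], [1.9, 2.1]])
        assert (vd.sd_between, vd.sd_within) == pytest.approx((sd_b, sd_w), abs=1e-12)

    def test_single_image_eye_contributes_to_between_only(self):
        cohort = make_cohort({("A", "r"): [1.0], ("B", "r"): [1.5, 1.7], ("C", "r"): [2.0, 2.2]})
        vd = variance_decomposition(cohort, "FD")
        assert vd.n_eyes == 3
        _, sd_w = decomposition_oracle([[1.5, 1.7], [2.0, 2.2]])
        assert vd.sd_within == pytest.approx(sd_w, abs=1e-12)

    def test_adjusted_icc_uses_reference_in_both_places(self):
        cohort = make_cohort({("A", "r"): [0.9, 1.1], ("B", "r"): [1.9, 2.1]})
        ref = 2.0
        vd = variance_decomposition(cohort, "FD", reference_sd_between=ref)
        assert vd.icc_adjusted == pytest.approx(ref**2 / (ref**2 + vd.sd_within**2), abs=1e-15)

    def test_fewer_than_two_eyes_raises(self):
        cohort = make_cohort({("A", "r"): [1.0, 1.1]})
        with pytest.raises(AnalysisError):
            variance_decomposition(cohort, "FD")

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_icc_identity_holds_exactly(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            ("S%d" % i, "r"): list(rng.normal(1.5 + 0.1 * rng.normal(), 0.05, rng.integers(2, 6)))
            for i in range(rng.integers(3, 8))
        }
        vd = variance_decomposition(make_cohort({k: [abs(v) + 0.5 for v in g] for k, g in groups.items()}), "FD")
        restated = 1.0 / (1.0 + (vd.sd_within / vd.sd_between) ** 2)
        assert vd.icc == pytest.approx(restated, abs=1e-12)


# -------------------------------------------------------------- reference SD

class TestCombinedReferenceSd:
    def test_idempotent_pooling(self, toy_cohort):
        single = combined_reference_sd([toy_cohort], "FD")
        doubled_means = combined_reference_sd([toy_cohort, toy_cohort], "FD")
        # pooling a cohort with itself duplicates every per-eye mean;
        # the SD shrinks only through the n-1 denominator
        means = [np.mean(e.values("FD")) for e in toy_cohort.eyes]
        expect = np.std(means + means, ddof=1)
        assert doubled_means == pytest.approx(expect, abs=1e-15)
        assert single == pytest.approx(np.std(means, ddof=1), abs=1e-15)

    def test_definition_on_two_cohorts(self):
        c1 = make_cohort({("A", "r"): [1.0, 1.0], ("B", "r"): [1.0, 1.0]}, name="c1")
        c2 = make_cohort({("C", "r"): [2.0, 2.0], ("D", "r"): [2.0, 2.0]}, name="c2")
        got = combined_reference_sd([c1, c2], "FD")
        assert got == pytest.approx(np.std([1, 1, 2, 2], ddof=1), abs=1e-15)


# --------------------------------------------------------- interchangeability

class TestInterchangeability:
    @staticmethod
    def _two_method_cohort(offset=0.0, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        from conftest import make_record
        from retrep.io import CohortTable, EyeSeries
        import pandas as pd

        eyes = []
        for i in range(10):
            truth = 1.5 + 0.1 * rng.normal()
            records = []
            for k in range(4):
                a = truth + noise * rng.normal()
                b = truth + offset + noise * rng.normal()
                records.append(
                    make_record(
                        f"S{i}", "right", f"S{i}_r_{k}",
                        pd.Timestamp("2022-01-01") + pd.Timedelta(minutes=k),
                        {"A": a, "B": b}, pbad=0.1 + 0.05 * k,
                    )
                )
            eyes.append(EyeSeries(subject_id=f"S{i}", eye="right", records=tuple(records)))
        return CohortTable(name="two", eyes=eyes)

    def test_self_agreement(self):
        cohort = self._two_method_cohort(offset=0.0, noise=0.0)
        r = interchangeability(cohort, "A", "B")
        assert r.pearson.estimate == pytest.approx(1.0, abs=1e-12)
        assert r.spearman.estimate == pytest.approx(1.0, abs=1e-12)
        assert r.bland_altman.mean_diff == pytest.approx(0.0, abs=1e-15)
        assert r.bland_altman.loa_high - r.bland_altman.loa_low == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset(self):
        cohort = self._two_method_cohort(offset=0.5, noise=0.0)
        r = interchangeability(cohort, "A", "B")
        assert r.pearson.estimate == pytest.approx(1.0, abs=1e-12)
        assert r.bland_altman.mean_diff == pytest.approx(-0.5, abs=1e-12)

    def test_per_eye_means_beat_single_images(self):
        # two methods sharing eye truth with independent noise: averaging
        # over images must raise the between-method correlation
        cohort = self._two_method_cohort(noise=0.05, seed=4)
        r = interchangeability(cohort, "A", "B", pbad_max=1.0)
        singles_a = [e.records[0].trait_values["A"] for e in cohort.eyes]
        singles_b = [e.records[0].trait_values["B"] for e in cohort.eyes]
        assert r.pearson.estimate > pearson_oracle(singles_a, singles_b)

    def test_quality_gate_excludes_bad_images(self):
        cohort = self._two_method_cohort(noise=0.0)
        r = interchangeability(cohort, "A", "B", pbad_max=0.2)
        # pbads are 0.10, 0.15, 0.20, 0.25 -> two images survive per eye
        assert r.n_images_used == 20

    def test_too_few_surviving_eyes_raises(self):
        cohort = self._two_method_cohort(noise=0.0)
        with pytest.raises(AnalysisError, match="survive"):
            interchangeability(cohort, "A", "B", pbad_max=0.05)
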