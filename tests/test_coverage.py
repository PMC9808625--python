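"""Capture-QC statistics against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import capturebias as cb


def _counts_from_coverages(coverages, panel):
    ids = panel.snp_ids[: len(coverages)]
    return cb.AlleleCounts.from_frame(
        pd.DataFrame(
            {
                "library": "L1",
                "assay": "a",
                "snp_id": ids,
                "ref_count": np.asarray(coverages, dtype=int),
                "alt_count": 0,
                "other_count": 0,
            }
        )
    )


class TestCoverageSummary:
    def test_constant_coverage_has_no_low_tail(self, small_panel):
        counts = _counts_from_coverages([7] * small_panel.n_snps, small_panel)
        summ = cb.coverage_summary(counts, small_panel, threshold=0.1)
        assert summ.fraction_below == 0.0
        assert summ.hist_mass.sum() == pytest.approx(1.0)

    def test_fraction_below_counts_directly(self):
        panel = cb.simulate_panel(4, 1, 1000, seed=0)
        counts = _counts_from_coverages([0, 0, 10, 10], panel)
        summ = cb.coverage_summary(counts, panel, threshold=0.1)
        assert summ.mean == 5.0
        assert summ.fraction_below == 0.5

    def test_lognormal_tail_matches_closed_form(self):
        """Fraction below 0.1x the mean for log-normal coverage matches the
        log-normal CDF evaluated at 0.1 E[X]."""
        sigma = 1.5
        n = 50_000
        panel = cb.simulate_panel(n, 10, 10_000_000, seed=31)
        rng = np.random.default_rng(31)
        cov = np.rint(np.exp(rng.normal(5.0, sigma, n))).astype(int)
        counts = _counts_from_coverages(cov, panel)
        summ = cb.coverage_summary(counts, panel, threshold=0.1)
        # closed form: P(X < 0.1 E[X]) for X log-normal(mu, sigma)
        oracle = stats.norm.cdf((np.log(0.1) + sigma**2 / 2) / sigma)
        assert summ.fraction_below == pytest.approx(oracle, abs=0.01)

    def test_empty_subset_rejected(self, small_panel):
        counts = _counts_from_coverages([1] * small_panel.n_snps, small_panel)
        small_panel.add_flag("nothing", np.zeros(small_panel.n_snps, bool))
        with pytest.raises(cb.EmptyInputError):
            cb.coverage_summary(counts, small_panel, flag="nothing")

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 9999),
        scale=st.integers(2, 50),
    )
    def test_fraction_below_invariant_under_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        panel = cb.simulate_panel(50, 1, 100_000, seed=seed)
        cov = rng.integers(0, 40, 50)
        if cov.sum() == 0:
            cov[0] = 1
        a = cb.coverage_summary(_counts_from_coverages(cov, panel), panel)
        b = cb.coverage_summary(_counts_from_coverages(cov * scale, panel), panel)
        assert a.fraction_below == b.fraction_below


class TestEnrichmentByDistance:
    def test_flat_track_ratio_one(self):
        prof = cb.enrichment_by_distance(np.full(401, 5.0), W=200)
        assert prof.center_ratio == 1.0

    def test_degenerate_window_rejected(self):
        with pytest.raises(cb.UndefinedRatioError):
            cb.enrichment_by_distance(np.array([1.0]), W=0)

    def test_zero_flank_coverage_rejected(self):
        track = np.zeros(401)
        track[200] = 10
        with pytest.raises(cb.UndefinedRatioError):
            cb.enrichment_by_distance(track, W=200)

    def test_simulated_decay_matches_kernel_expectation(self):
        """Center ratio of a simulated capture matches direct numerical
        evaluation of the distance-decay kernel (exponential decay with
        halfwidth h applied to the molecule-to-target gap, integrated over
        the offset and fragment-length distributions)."""
        h = 50.0
        median, log_sd, W = 55.0, 0.25, 200
        panel = cb.simulate_panel(400, 1, 10_000_000, seed=41)
        truth = cb.GenotypeTruth(
            panel=panel,
            genotypes=np.zeros((1, 400), dtype=np.int8),
            populations=["p"],
            p_ancestral=np.full(400, 0.5),
        )
        assay = cb.AssayProfile(name="decay", offtarget_halfwidth=h)
        lib = cb.LibraryProfile(name="L1", complexity=2_000_000)
        res = cb.simulate_capture(truth, lib, assay, 400_000, seed=41)
        prof = cb.enrichment_by_distance(res.coverage, W=W)

        # oracle: expected coverage at offsets {0, +-100} by direct summation
        lengths = np.arange(30, 301)
        edges = np.concatenate([[0.0], lengths + 0.5])
        pmf = np.diff(stats.lognorm.cdf(edges, s=log_sd, scale=median))
        pmf /= pmf.sum()
        offsets = np.arange(-W, W + 1)
        expected = {}
        for x in (0, -100, 100):
            acc = 0.0
            for L, pL in zip(lengths, pmf):
                start = offsets - L // 2
                end = start + L
                gap = np.maximum(np.maximum(start, 1 - end), 0)
                covers_x = (start <= x) & (end > x)
                acc += pL * np.sum(np.exp(-gap / h) * covers_x)
            expected[x] = acc
        oracle = expected[0] / (0.5 * (expected[-100] + expected[100]))
        assert prof.center_ratio == pytest.approx(oracle, rel=0.10)


class TestCompositionShift:
    def test_gc_fraction_definition(self):
        assert cb.gc_fraction("GCGC") == 1.0
        assert cb.gc_fraction("ATAT") == 0.0
        assert cb.gc_fraction("ACGT") == 0.5

    def test_identical_records_have_zero_shift(self):
        rec = pd.DataFrame({"gc": [0.3, 0.5, 0.7], "length": [40, 50, 60]})
        for stat in ("gc", "length"):
            shift = cb.composition_shift(rec, rec, statistic=stat)
            assert shift.median_shift == 0.0 and shift.mean_shift == 0.0

    def test_empty_records_rejected(self):
        rec = pd.DataFrame({"gc": [0.5], "length": [50]})
        with pytest.raises(cb.EmptyInputError):
            cb.composition_shift(rec.iloc[:0], rec)

    def test_uniform_subsample_shows_no_shift(self):
        rng = np.random.default_rng(51)
        base = pd.DataFrame(
            {"length": rng.integers(30, 100, 20_000), "gc": rng.random(20_000)}
        )
        sub = base.sample(n=4000, random_state=7)
        shift = cb.composition_shift(sub, base, statistic="length")
        se = base["length"].std() / np.sqrt(4000)
        assert abs(shift.mean_shift) < 4 * se

    def test_length_preference_shifts_median_to_oracle(self):
        """A positive logistic length slope enriches longer fragments; the
        enriched median matches the weighted-resampling expectation."""
        slope, mid = 0.08, 55.0
        panel = cb.simulate_panel(200, 1, 10_000_000, seed=61)
        truth = cb.GenotypeTruth(
            panel=panel,
            genotypes=np.zeros((1, 200), dtype=np.int8),
            populations=["p"],
            p_ancestral=np.full(200, 0.5),
        )
        lib = cb.LibraryProfile(name="L1", complexity=1_000_000)
        flat = cb.AssayProfile(name="flat", offtarget_halfwidth=1e9)
        sloped = cb.AssayProfile(
            name="long", length_slope=slope, length_midpoint=mid,
            offtarget_halfwidth=1e9,
        )
        base = cb.simulate_capture(truth, lib, flat, 100_000, seed=61)
        enr = cb.simulate_capture(truth, lib, sloped, 100_000, seed=61)
        shift = cb.composition_shift(enr.reads, base.reads, statistic="length")
        assert shift.median_shift > 0
        # oracle: weighted median of the fragment-length law under the
        # logistic capture response
        lengths = np.arange(30, 301)
        edges = np.concatenate([[0.0], lengths + 0.5])
        pmf = np.diff(stats.lognorm.cdf(edges, s=0.25, scale=55.0))
        w = pmf / (1 + np.exp(-slope * (lengths - mid)))
        cdf = np.cumsum(w) / w.sum()
        oracle_median = lengths[np.searchsorted(cdf, 0.5)]
        assert shift.assay_median == pytest.approx(oracle_median, abs=2)


class TestSaturation:
    def test_zero_and_full_depth(self):
        reads = pd.DataFrame(
            {"snp_id": ["a", "a", "b", "c"], "molecule": [1, 1, 2, 3]}
        )
        curve = cb.saturation_curve(reads, [0, 4], seed=1)
        assert curve["n_snps"].tolist() == [0, 3]

    def test_curve_monotone(self):
        rng = np.random.default_rng(71)
        reads = pd.DataFrame(
            {
                "snp_id": rng.integers(0, 50, 500).astype(str),
                "molecule": np.arange(500),
            }
        )
        curve = cb.saturation_curve(reads, [0, 50, 100, 250, 500], seed=2)
        assert (np.diff(curve["n_snps"]) >= 0).all()

    def test_depth_beyond_reads_rejected(self):
        reads = pd.DataFrame({"snp_id": ["a"], "molecule": [0]})
        with pytest.raises(cb.ValidationError):
            cb.saturation_curve(reads, [2], seed=1)

    def test_poisson_coverage_matches_zero_class(self):
        """With ~Poisson(lam) reads per SNP, the covered fraction at full
        depth is 1 - exp(-lam) (Poisson zero class)."""
        lam, n_snps = 1.0, 20_000
        rng = np.random.default_rng(81)
        n_reads = int(lam * n_snps)
        reads = pd.DataFrame(
            {
                "snp_id": rng.integers(0, n_snps, n_reads).astype(str),
                "molecule": np.arange(n_reads),
            }
        )
        curve = cb.saturation_curve(reads, [n_reads], seed=3)
        covered = curve["n_snps"].iloc[0] / n_snps
        assert covered == pytest.approx(1 - np.exp(-lam), abs=0.01)

    def test_concave_in_expectation(self):
        """Replicate-mean saturation gains shrink with depth."""
        means = np.zeros(4)
        for r in range(30):
            rng = np.random.default_rng(900 + r)
            reads = pd.DataFrame(
                {
                    "snp_id": rng.integers(0, 200, 2000).astype(str),
                    "molecule": np.arange(2000),
                }
            )
            curve = cb.saturation_curve(reads, [0, 400, 800, 1200], seed=r)
            means += curve["n_snps"].to_numpy() / 30
        gains = np.diff(means)
        assert (np.diff(gains) < 0).all()


class TestRelativeCoverage:
    def _with_flags(self, coverages, split):
        panel = cb.simulate_panel(len(coverages), 1, 10_000_000, seed=91)
        panel.add_flag("core", np.arange(len(coverages)) < split)
        panel.add_flag("extra", np.arange(len(coverages)) >= split)
        return panel, _counts_from_coverages(coverages, panel)

    def test_core_against_itself_is_one(self):
        panel, counts = self._with_flags([3, 5, 7, 9], 4)
        assert cb.relative_coverage(counts, panel, "core", "core") == 1.0

    def test_doubled_subset_is_two(self):
        panel, counts = self._with_flags([4, 4, 8, 8], 2)
        assert cb.relative_coverage(counts, panel, "extra", "core") == 2.0

    def test_zero_core_mean_rejected(self):
        panel, counts = self._with_flags([0, 0, 5, 5], 2)
        with pytest.raises(cb.UndefinedRatioError):
            cb.relative_coverage(counts, panel, "extra", "core")

    def test_downweighted_subset_recovers_scale(self):
        """A subset captured at 0.3x efficiency shows ~0.3 relative mean
        coverage (simulation ground truth)."""
        n = 2000
        panel = cb.simulate_panel(n, 2, 10_000_000, seed=95)
        truth = cb.GenotypeTruth(
            panel=panel,
            genotypes=np.zeros((1, n), dtype=np.int8),
            populations=["p"],
            p_ancestral=np.full(n, 0.5),
        )
        weak = np.arange(n) % 4 == 0
        panel.add_flag("weak", weak)
        panel.add_flag("core", ~weak)
        scale = np.where(weak, 0.3, 1.0)
        lib = cb.LibraryProfile(name="L1", complexity=2_000_000)
        assay = cb.AssayProfile(name="flat", offtarget_halfwidth=1e9)
        res = cb.simulate_capture(
            truth, lib, assay, 300_000, seed=95, efficiency_scale=scale
        )
        ratio = cb.relative_coverage(res.counts, panel, "weak", "core")
        assert ratio == pytest.approx(0.3, rel=0.10)


class TestNearTargetAnnotation:
    def test_thresholds_are_inclusive(self):
        cov = pd.Series({"a": 5.0, "b": 4.9})
        freqs = pd.DataFrame({"EUR": [0.05, 0.5]}, index=["a", "b"])
        passing, n = cb.near_target_annotation(cov, core_mean=10.0, freqs=freqs)
        assert list(passing) == ["a"] and n == 1  # 0.50 and maf 0.05 pass

    def test_below_coverage_threshold_excluded(self):
        cov = pd.Series({"a": 4.9})
        freqs = pd.DataFrame({"EUR": [0.5]}, index=["a"])
        _, n = cb.near_target_annotation(cov, core_mean=10.0, freqs=freqs)
        assert n == 0

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(101)
        ids = [f"s{i}" for i in range(500)]
        cov = pd.Series(rng.uniform(0, 12, 500), index=ids)
        freqs = pd.DataFrame(
            {
                "EUR": rng.uniform(0, 1, 500),
                "AFR": np.where(rng.random(500) < 0.3, np.nan,
                                rng.uniform(0, 1, 500)),
            },
            index=ids,
        )
        core_mean = 6.0
        passing, _ = cb.near_target_annotation(cov, core_mean, freqs)
        expected = set()
        for s in ids:
            mafs = []
            for pop in ("EUR", "AFR"):
                f = freqs.loc[s, pop]
                if not np.isnan(f):
                    mafs.append(min(f, 1 - f))
            if cov[s] / core_mean >= 0.5 and any(m >= 0.05 for m in mafs):
                expected.add(s)
        assert set(passing) == expected
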