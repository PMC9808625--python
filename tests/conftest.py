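import numpy as np
import pandas as pd
import pytest

import capturebias as cb


@pytest.fixture(scope="session")
def small_panel():
    return cb.simulate_panel(200, n_chromosomes=2, chrom_length=1_000_000, seed=7)


@pytest.fixture
def make_counts():
    """Factory building a validated counts table from row tuples."""

    def _make(rows, columns=("library", "assay", "snp_id", "ref_count",
                             "alt_count", "other_count")):
        return cb.AlleleCounts.from_frame(
            pd.DataFrame(list(rows), columns=list(columns))
        )

    return _make


def filter_pipeline_replicate(panel, r, bias_sds=(0.15, 0.11)):
    """Full synthetic pipeline: genotypes -> counts -> rates -> filter -> scan.

    Four scan libraries (one individual each) are captured with two assays
    whose per-SNP allelic biases are shared across libraries; ten further
    libraries provide the pooled heterozygous-site rates that build the
    cross-platform filter.  Returns the before/after scan summaries and the
    filter pass fraction.
    """
    truth = cb.simulate_genotypes(panel, {"pop": 14}, seed=1000 + r)
    effA = cb.draw_assay_effects(
        panel, cb.AssayProfile(name="capA", bias_mean=0.52, bias_sd=bias_sds[0]),
        seed=2000 + r,
    )
    effB = cb.draw_assay_effects(
        panel, cb.AssayProfile(name="capB", bias_mean=0.52, bias_sd=bias_sds[1]),
        seed=2000 + r,
    )
    scan_libs, scan_inds = [f"L{i}" for i in range(4)], [0, 1, 2, 3]
    ref_libs, ref_inds = [f"R{i}" for i in range(10)], list(range(4, 14))
    cA = cb.simulate_read_counts(
        truth, "capA", beta=effA.per_snp_beta, mean_depth=5, seed=3000 + r,
        library_names=scan_libs, individuals=scan_inds,
    )
    cB = cb.simulate_read_counts(
        truth, "capB", beta=effB.per_snp_beta, mean_depth=5, seed=4000 + r,
        library_names=scan_libs, individuals=scan_inds,
    )
    rA = cb.simulate_read_counts(
        truth, "capA", beta=effA.per_snp_beta, mean_depth=10, seed=5000 + r,
        library_names=ref_libs, individuals=ref_inds,
    )
    rB = cb.simulate_read_counts(
        truth, "capB", beta=effB.per_snp_beta, mean_depth=10, seed=6000 + r,
        library_names=ref_libs, individuals=ref_inds,
    )
    het = cb.het_pairs_from_truth(truth, ref_libs, ref_inds)
    flag, frac = cb.build_filter(
        cb.refmatch_rates(rA, het), cb.refmatch_rates(rB, het), max_diff=0.04
    )
    counts = cb.AlleleCounts.from_frame(
        pd.concat([cA.df, cB.df], ignore_index=True)
    )
    matrix = cb.pseudohaploid_call(
        counts, panel, seed=7000 + r, block_bp=4_000_000
    )
    out = cb.evaluate_filter(matrix, flag, [("capA", "capB")])[("capA", "capB")]
    return out, frac


@pytest.fixture
def het_truth_panel():
    """Panel plus one individual heterozygous at every SNP."""

    def _make(n_snps, seed=0):
        panel = cb.simulate_panel(n_snps, 1, 10_000_000, seed=seed)
        truth = cb.GenotypeTruth(
            panel=panel,
            genotypes=np.ones((1, n_snps), dtype=np.int8),
            populations=["pop"],
            p_ancestral=np.full(n_snps, 0.5),
        )
        return panel, truth

    return _make
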