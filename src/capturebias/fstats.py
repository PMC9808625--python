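"""Pseudohaploid calling and f4 symmetry statistics.

Ancient-DNA samples are routinely represented *pseudohaploidly*: at each
SNP a single random read supplies the allele, sidestepping genotype
calling at low coverage.  Given four pseudohaploid samples a, b, c, d the
f4 statistic is the average over SNPs of ``(a_s - b_s)(c_s - d_s)`` with
``1`` = reference allele sampled.  When the same library is captured with
two reagents, the statistic

    f4(lib1-reagent1, lib1-reagent2; lib2-reagent1, lib2-reagent2)

is zero in expectation unless the reagents impose per-SNP allelic biases
shared across libraries — then alleles co-occur between libraries
processed with the same reagent more often than chance, pushing the
statistic positive.  Standard errors come from a weighted block jackknife
over contiguous genomic blocks, which is robust to linkage between nearby
SNPs; the test is one-sided (bias predicts positive f4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .counts import AlleleCounts
from .errors import EmptyInputError, ValidationError
from .panel import SnpPanel

MISSING_CALL = -1


@dataclass
class PseudohaploidMatrix:
    """Pseudohaploid calls for (library, assay) samples over a panel.

    ``calls`` holds 1 (reference allele sampled), 0 (alternative) or
    :data:`MISSING_CALL`; ``blocks`` assigns each SNP to a contiguous
    genomic block for the jackknife.
    """

    calls: np.ndarray  # (n_samples, n_snps) int8
    samples: list[tuple[str, str]]  # (library, assay)
    snp_ids: np.ndarray
    blocks: np.ndarray

    def sample_index(self, library: str, assay: str) -> int:
        try:
            return self.samples.index((library, assay))
        except ValueError:
            raise ValidationError(f"no sample for ({library!r}, {assay!r})") from None

    def row(self, library: str, assay: str) -> np.ndarray:
        return self.calls[self.sample_index(library, assay)]

    @property
    def libraries(self) -> list[str]:
        return sorted({lib for lib, _ in self.samples})

    @property
    def assays(self) -> list[str]:
        return sorted({assay for _, assay in self.samples})


@dataclass
class F4Result:
    f4: float
    se: float  # nan when fewer than 2 non-empty blocks
    z: float  # nan when se is 0 or undefined
    n_snps: int
    n_blocks: int


def assign_blocks(panel: SnpPanel, block_bp: int = 5_000_000) -> np.ndarray:
    """Contiguous genomic blocks of fixed span, numbered over the panel."""
    if block_bp < 1:
        raise ValidationError("block_bp must be >= 1")
    chrom = panel.df["chrom"].to_numpy()
    pos = panel.df["pos"].to_numpy()
    raw = pos // block_bp
    # renumber (chromosome, bin) pairs contiguously in panel order
    key = pd.factorize(pd.Series(chrom).astype(str) + ":" + pd.Series(raw).astype(str))[0]
    return key.astype(np.int64)


def assign_blocks_by_count(panel: SnpPanel, n_blocks: int) -> np.ndarray:
    """Fallback for unplaced panels: equal-count contiguous SNP blocks."""
    if n_blocks < 1:
        raise ValidationError("n_blocks must be >= 1")
    return (np.arange(panel.n_snps) * n_blocks // max(panel.n_snps, 1)).astype(
        np.int64
    )


def pseudohaploid_call(
    counts: AlleleCounts,
    panel: SnpPanel,
    seed: int = 0,
    dedup: str = "post",
    block_bp: int = 5_000_000,
) -> PseudohaploidMatrix:
    """One random read per SNP for every (library, assay) sample.

    At each SNP with at least one ref or alt read the call is the reference
    allele with probability ``ref / (ref + alt)``, i.e. a uniformly random
    read among the allele-informative ones; SNPs with no such reads are
    missing.  Each sample draws from its own random stream derived from the
    master seed and the (library, assay) labels, so calls are reproducible
    and independent across samples.  Post-deduplication counts are used by
    default (one molecule, one vote).
    """
    sel = counts.select(dedup=dedup)
    df = sel.df
    samples = sorted(
        {(str(l), str(a)) for l, a in zip(df["library"], df["assay"])}
    )
    calls = np.full((len(samples), panel.n_snps), MISSING_CALL, dtype=np.int8)
    for si, (lib, assay) in enumerate(samples):
        sub = df[(df["library"] == lib) & (df["assay"] == assay)]
        grouped = sub.groupby("snp_id")[["ref_count", "alt_count"]].sum()
        total = grouped["ref_count"] + grouped["alt_count"]
        grouped = grouped[total > 0]
        if len(grouped) == 0:
            continue
        idx = panel.index_of(grouped.index.to_numpy())
        p_ref = grouped["ref_count"].to_numpy() / (
            grouped["ref_count"] + grouped["alt_count"]
        ).to_numpy()
        rng = child_rng(seed, "pseudohaploid", lib, assay)
        calls[si, idx] = (rng.random(len(p_ref)) < p_ref).astype(np.int8)
    return PseudohaploidMatrix(
        calls=calls,
        samples=samples,
        snp_ids=panel.snp_ids,
        blocks=assign_blocks(panel, block_bp=block_bp),
    )


def f4(a, b, c, d, blocks) -> F4Result:
    """f4 with weighted block-jackknife standard error.

    Inputs are call vectors over the same SNPs (int with -1 missing, or
    float with NaN missing); a SNP is used only when all four samples are
    non-missing there.  The jackknife deletes one genomic block at a time,
    weights blocks by their used-SNP counts, and uses the Busing-style
    variance for unequal block sizes, which reduces to the classic
    delete-one jackknife for equal blocks.
    """
    vecs = [np.asarray(v, dtype=float) for v in (a, b, c, d)]
    blocks = np.asarray(blocks)
    if any(v.shape != blocks.shape for v in vecs):
        raise ValidationError("call vectors and blocks must share one length")
    missing = np.zeros(blocks.shape, dtype=bool)
    for v in vecs:
        missing |= ~np.isfinite(v) | (v < 0)
    use = ~missing
    n = int(use.sum())
    if n == 0:
        raise EmptyInputError("no SNP where all four samples are non-missing")
    terms = (vecs[0][use] - vecs[1][use]) * (vecs[2][use] - vecs[3][use])
    total = terms.sum()
    est = total / n

    blk = blocks[use]
    uniq, inv = np.unique(blk, return_inverse=True)
    m = np.bincount(inv).astype(float)  # per-block used-SNP counts
    G = len(uniq)
    if G < 2:
        return F4Result(f4=float(est), se=float("nan"), z=float("nan"),
                        n_snps=n, n_blocks=G)
    block_sum = np.bincount(inv, weights=terms)
    loo = (total - block_sum) / (n - m)  # leave-one-block-out estimates
    h = n / m
    theta_j = G * est - float(((1.0 - m / n) * loo).sum())
    pseudo = h * est - (h - 1.0) * loo
    var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / G)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(est / se) if se > 0 else float("nan")
    return F4Result(f4=float(est), se=se, z=z, n_snps=n, n_blocks=G)


def symmetry_scan(
    matrix: PseudohaploidMatrix,
    assay_a: str,
    assay_b: str,
    snp_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """All-pairs library symmetry test between two assays (or data types).

    For every unordered library pair {1, 2} with both assays present,
    computes ``f4(lib1-assayA, lib1-assayB; lib2-assayA, lib2-assayB)``:
    L libraries give L(L-1)/2 statistics.  Libraries missing one assay are
    excluded with a warning.  ``snp_mask`` optionally restricts the scan to
    a panel subset (e.g. a bias-filter flag).  Returns the per-pair table
    and a summary with the mean/quartile Z-scores needed for box plots.
    """
    have = {}
    for lib in {l for l, _ in matrix.samples}:
        have[lib] = {a for l, a in matrix.samples if l == lib}
    libs = sorted(l for l, assays in have.items() if {assay_a, assay_b} <= assays)
    dropped = sorted(set(have) - set(libs))
    if dropped:
        warnings.warn(
            f"libraries missing one assay were excluded: {dropped}", stacklevel=2
        )
    if len(libs) < 2:
        raise EmptyInputError("need at least two libraries with both assays")
    if snp_mask is not None:
        snp_mask = np.asarray(snp_mask, dtype=bool)
        if snp_mask.shape != matrix.blocks.shape:
            raise ValidationError("snp_mask misaligned with matrix SNPs")
    else:
        snp_mask = np.ones(matrix.blocks.shape, dtype=bool)
    blocks = matrix.blocks[snp_mask]
    rows = []
    for i in range(len(libs)):
        for j in range(i + 1, len(libs)):
            l1, l2 = libs[i], libs[j]
            res = f4(
                matrix.row(l1, assay_a)[snp_mask],
                matrix.row(l1, assay_b)[snp_mask],
                matrix.row(l2, assay_a)[snp_mask],
                matrix.row(l2, assay_b)[snp_mask],
                blocks,
            )
            rows.append(
                {
                    "lib1": l1,
                    "lib2": l2,
                    "f4": res.f4,
                    "se": res.se,
                    "z": res.z,
                    "n_snps": res.n_snps,
                    "n_blocks": res.n_blocks,
                }
            )
    table = pd.DataFrame(rows)
    z = table["z"].to_numpy(dtype=float)
    summary = {
        "n_pairs": len(table),
        "mean_f4": float(np.nanmean(table["f4"])),
        "mean_z": float(np.nanmean(z)),
        "min_z": float(np.nanmin(z)),
        "q25_z": float(np.nanquantile(z, 0.25)),
        "median_z": float(np.nanquantile(z, 0.5)),
        "q75_z": float(np.nanquantile(z, 0.75)),
        "max_z": float(np.nanmax(z)),
    }
    return table, summary
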