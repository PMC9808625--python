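"""Capture-QC statistics.

Quantifies how well an enrichment experiment worked: homogeneity of
coverage across targets (and the fraction of poorly enriched SNPs),
enrichment as a function of distance from the targeted position, shifts in
fragment GC content and length relative to an unenriched baseline,
saturation of unique SNPs under downsampling, relative coverage of panel
subsets, and the annotation of well-enriched near-target SNPs.

Coverage metrics default to pre-deduplication counts, because they measure
the effectiveness of enrichment per sequenced molecule; yield metrics
(saturation) operate on distinct molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from ._rng import child_rng
from .counts import AlleleCounts
from .errors import EmptyInputError, UndefinedRatioError, ValidationError
from .panel import SnpPanel


def expected_informative_reads(
    total_reads: float, endogenous_fraction: float, on_target_rate: float
) -> float:
    """Expected number of reads overlapping targeted SNPs without enrichment.

    The product of the total sequenced reads, the fraction of them deriving
    from the target organism, and the probability that a mapped read
    overlaps a targeted SNP.  E.g. 400 million reads from a 1%-endogenous
    library with a 1-in-100 on-target rate yield 40,000 informative reads —
    the arithmetic that motivates enrichment in the first place.
    """
    return float(total_reads) * endogenous_fraction * on_target_rate


def gc_fraction(sequence: str) -> float:
    """Fraction of G/C nucleotides in a read sequence."""
    return _bio_gc_fraction(sequence)


# ---------------------------------------------------------------------- #
# coverage homogeneity
# ---------------------------------------------------------------------- #
@dataclass
class CoverageSummary:
    coverage: np.ndarray  # per-SNP total reads, panel subset order
    mean: float
    hist_edges: np.ndarray  # histogram of coverage / mean
    hist_mass: np.ndarray  # masses sum to 1
    fraction_below: float
    threshold: float


def coverage_summary(
    counts: AlleleCounts,
    panel: SnpPanel,
    flag: str | None = None,
    threshold: float = 0.1,
    dedup: str = "pre",
    library: str | None = None,
    assay: str | None = None,
    n_bins: int = 50,
) -> CoverageSummary:
    """Per-SNP coverage distribution and the fraction below ``threshold x mean``.

    Coverage at a SNP is ref+alt+other reads summed over the selected rows;
    panel SNPs with no counts have coverage 0.  ``flag`` restricts to a
    panel subset.
    """
    sel = counts.select(library=library, assay=assay, dedup=dedup)
    cov = sel.coverage(panel).to_numpy(dtype=float)
    if flag is not None:
        cov = cov[panel.flag(flag)]
    if cov.size == 0:
        raise EmptyInputError("no SNPs in the requested subset")
    mean = cov.mean()
    if mean <= 0:
        raise EmptyInputError("mean coverage is zero in the requested subset")
    rel = cov / mean
    mass, edges = np.histogram(rel, bins=n_bins)
    return CoverageSummary(
        coverage=cov,
        mean=float(mean),
        hist_edges=edges,
        hist_mass=mass / cov.size,
        fraction_below=float(np.mean(cov < threshold * mean)),
        threshold=threshold,
    )


# ---------------------------------------------------------------------- #
# enrichment by distance
# ---------------------------------------------------------------------- #
@dataclass
class DistanceProfile:
    offsets: np.ndarray
    coverage: np.ndarray
    center_ratio: float  # coverage at 0 over mean coverage at +-100 bp


def enrichment_by_distance(track: np.ndarray, W: int) -> DistanceProfile:
    """Mean per-base coverage by offset from the target, and the center ratio.

    ``track`` must cover offsets ``-W..W`` (length ``2W + 1``).  The center
    ratio compares coverage at the targeted position with the mean coverage
    100 bp away on either side, so it requires ``W >= 100`` and nonzero
    coverage at the +-100 offsets.
    """
    track = np.asarray(track, dtype=float)
    if track.shape != (2 * W + 1,):
        raise ValidationError(f"track must have length {2 * W + 1} for W={W}")
    if W < 100:
        raise UndefinedRatioError(
            "center ratio is defined against offsets +-100 bp; need W >= 100"
        )
    denom = 0.5 * (track[W - 100] + track[W + 100])
    if denom <= 0:
        raise UndefinedRatioError("zero coverage at offsets +-100 bp")
    return DistanceProfile(
        offsets=np.arange(-W, W + 1),
        coverage=track,
        center_ratio=float(track[W] / denom),
    )


# ---------------------------------------------------------------------- #
# GC / length composition shifts
# ---------------------------------------------------------------------- #
@dataclass
class CompositionShift:
    statistic: str
    baseline_median: float
    assay_median: float
    median_shift: float
    mean_shift: float
    baseline_values: np.ndarray
    assay_values: np.ndarray


def composition_shift(
    assay_records: pd.DataFrame,
    baseline_records: pd.DataFrame,
    statistic: str = "gc",
) -> CompositionShift:
    """Shift of read GC content or length relative to an unenriched baseline.

    Both inputs are per-read tables with ``gc`` (fraction in [0, 1]) and
    ``length`` (bp) columns, e.g. the ``reads`` frame of a capture result.
    """
    if statistic not in ("gc", "length"):
        raise ValidationError("statistic must be 'gc' or 'length'")
    a = np.asarray(assay_records[statistic], dtype=float)
    b = np.asarray(baseline_records[statistic], dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("both record sets must be nonempty")
    return CompositionShift(
        statistic=statistic,
        baseline_median=float(np.median(b)),
        assay_median=float(np.median(a)),
        median_shift=float(np.median(a) - np.median(b)),
        mean_shift=float(a.mean() - b.mean()),
        baseline_values=b,
        assay_values=a,
    )


# ---------------------------------------------------------------------- #
# saturation under downsampling
# ---------------------------------------------------------------------- #
def saturation_curve(
    reads: pd.DataFrame, depths, seed: int = 0
) -> pd.DataFrame:
    """Unique SNPs (>= 1 distinct molecule) at downsampled read totals.

    ``reads`` is a per-read table with ``snp_id`` and ``molecule`` columns;
    only reads overlapping their SNP should be passed (filter on the
    ``covers`` column of a capture result first).  Downsampling draws reads
    without replacement: one random permutation is drawn and each requested
    depth reads off its prefix, so all depths describe subsamples of the
    same hypothetical resequencing run and the curve is monotone by
    construction.
    """
    depths = np.asarray(list(depths), dtype=np.int64)
    n = len(reads)
    if (depths < 0).any():
        raise ValidationError("depths must be >= 0")
    if (depths > n).any():
        raise ValidationError(f"requested depth exceeds the {n} available reads")
    rng = child_rng(seed, "saturation")
    perm = rng.permutation(n)
    snp_codes = pd.factorize(reads["snp_id"].to_numpy())[0][perm]
    # first time each SNP appears along the permutation
    first_seen = np.full(snp_codes.max() + 1 if n else 0, n, dtype=np.int64)
    np.minimum.at(first_seen, snp_codes, np.arange(n))
    first_sorted = np.sort(first_seen)
    out = []
    for d in depths:
        out.append(int(np.searchsorted(first_sorted, d, side="left")))
    return pd.DataFrame({"depth": depths, "n_snps": out})


# ---------------------------------------------------------------------- #
# subset relative coverage and near-target annotation
# ---------------------------------------------------------------------- #
def relative_coverage(
    counts: AlleleCounts,
    panel: SnpPanel,
    numerator_flag: str,
    core_flag: str,
    dedup: str = "pre",
) -> float:
    """Mean coverage of one panel subset relative to the core subset."""
    cov = counts.select(dedup=dedup).coverage(panel).to_numpy(dtype=float)
    num_mask = panel.flag(numerator_flag)
    core_mask = panel.flag(core_flag)
    if not num_mask.any() or not core_mask.any():
        raise EmptyInputError("both subsets must be nonempty")
    core_mean = cov[core_mask].mean()
    if core_mean <= 0:
        raise UndefinedRatioError("core subset has zero mean coverage")
    return float(cov[num_mask].mean() / core_mean)


def near_target_annotation(
    coverages: pd.Series,
    core_mean: float,
    freqs: pd.DataFrame,
    rel_cov_min: float = 0.5,
    maf_min: float = 0.05,
) -> tuple[pd.Index, int]:
    """Off-target SNPs enriched and polymorphic enough to be analyzable.

    A SNP passes iff its coverage is at least ``rel_cov_min`` of the core
    mean coverage AND its minor-allele frequency is at least ``maf_min`` in
    at least one population (columns of ``freqs``; NaN = frequency unknown
    in that population).  Both thresholds are inclusive.  Returns the
    passing SNP index and its size.
    """
    if core_mean <= 0:
        raise UndefinedRatioError("core mean coverage must be > 0")
    coverages = coverages.astype(float)
    freqs = freqs.reindex(coverages.index)
    if freqs.notna().sum(axis=1).eq(0).any():
        raise ValidationError(
            "every SNP needs an allele frequency in at least one population"
        )
    maf = np.minimum(freqs, 1.0 - freqs)
    well_covered = coverages / core_mean >= rel_cov_min
    polymorphic = (maf >= maf_min).any(axis=1)
    passing = coverages.index[well_covered & polymorphic]
    return passing, len(passing)
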