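"""Synthetic multi-library, multi-assay SNP-capture experiments.

The generator produces, with known ground truth, the phenomena the analysis
modules are built to measure:

* per-SNP enrichment-efficiency heterogeneity (a log-normal efficiency with
  mean 1 and spread ``efficiency_spread``), which drives the shape of the
  coverage histogram and the fraction of poorly enriched targets;
* per-SNP allelic bias at heterozygous sites: each assay draws, once, a
  reference-read probability ``beta_s`` per SNP from a truncated normal.
  Because the draw is keyed by the assay (not the library), two libraries
  captured with the same reagent share their biases — exactly the mechanism
  that creates artifactual affinity in f4 symmetry tests;
* a logistic capture response to fragment length and a quadratic (Gaussian)
  response to fragment GC fraction;
* exponential decay of capture efficiency with distance from the targeted
  position;
* finite library complexity: reads are drawn with replacement from a finite
  pool of distinct molecules, so PCR duplicates arise naturally and
  post-deduplication counts saturate at the library's complexity.

Reads are abstract records (SNP, allele, molecule id, length, GC); no
sequences are simulated and no alignment is performed, because every
downstream analysis consumes counts.  Reference bias common to all
platforms (mapping bias) is folded into ``bias_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .counts import AlleleCounts
from .errors import InfeasibleError, ValidationError
from .panel import SnpPanel

# fragment-length classes used throughout (bp); last bin is open-ended
LENGTH_BIN_EDGES = (30, 40, 50, 60, 70)
LENGTH_BIN_LABELS = ("30-40", "40-50", "50-60", "60-70", "70+")

# fragment GC fractions are Beta-distributed around the genome-wide mean
GC_MEAN = 0.41
GC_CONCENTRATION = 35.0

# above this complexity the molecule pool is not materialized; every read is
# treated as a distinct molecule (collision probability < n_reads^2 / pool)
POOL_CAP = 10_000_000

ORDERED_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]


def assign_length_bin(lengths) -> np.ndarray:
    """Index of the fragment-length class for each length (lengths >= 30)."""
    return np.digitize(np.asarray(lengths), LENGTH_BIN_EDGES[1:])


# ---------------------------------------------------------------------- #
# profiles
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class AssayProfile:
    """Simulation parameters for one capture platform.

    ``efficiency_spread`` is the log-SD of the per-SNP enrichment efficiency
    (log-normal, mean fixed at 1).  ``bias_mean``/``bias_sd`` parameterize
    the truncated-normal (support [0.01, 0.99]) distribution of the per-SNP
    reference-read probability at heterozygous sites; ``bias_sd_by_length``
    optionally overrides the SD per fragment-length class (mapping from the
    labels in :data:`LENGTH_BIN_LABELS`).  The length response is logistic
    with midpoint ``length_midpoint`` (bp) and slope ``length_slope``
    (per bp); the GC response is ``exp(-gc_curvature * (gc - gc_optimum)^2)``;
    capture efficiency decays as ``exp(-d / offtarget_halfwidth)`` with the
    distance ``d`` (bp) between a molecule and its target.
    """

    name: str
    efficiency_spread: float = 0.0
    bias_mean: float = 0.5
    bias_sd: float = 0.0
    bias_sd_by_length: dict | None = None
    length_midpoint: float = 50.0
    length_slope: float = 0.0
    gc_optimum: float = 0.5
    gc_curvature: float = 0.0
    offtarget_halfwidth: float = 50.0

    def __post_init__(self):
        if self.efficiency_spread < 0:
            raise ValidationError("efficiency_spread must be >= 0")
        if not 0 < self.bias_mean < 1:
            raise ValidationError("bias_mean must be in (0, 1)")
        if self.bias_sd < 0:
            raise ValidationError("bias_sd must be >= 0")
        if self.offtarget_halfwidth <= 0:
            raise ValidationError("offtarget_halfwidth must be > 0")


@dataclass(frozen=True)
class LibraryProfile:
    """One sequencing library: complexity, endogenous content, fragments."""

    name: str
    strandedness: str = "double"
    endogenous_fraction: float = 1.0
    complexity: int = 100_000
    fragment_median: float = 55.0
    fragment_log_sd: float = 0.25
    individual: int = 0  # column of the genotype-truth matrix

    def __post_init__(self):
        if not 0 < self.endogenous_fraction <= 1:
            raise ValidationError("endogenous_fraction must be in (0, 1]")
        if self.complexity < 1:
            raise ValidationError("complexity must be >= 1")
        if self.strandedness not in ("single", "double"):
            raise ValidationError("strandedness must be 'single' or 'double'")


@dataclass
class GenotypeTruth:
    """Known diploid genotypes (alt-allele copies) for simulated individuals.

    Population structure follows the Balding–Nichols model: an ancestral
    alternative-allele frequency ``p0 ~ Uniform(0.05, 0.95)`` per SNP, and a
    per-population frequency drawn from
    ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` for drift parameter ``F > 0``
    (equal to ``p0`` when ``F = 0``).
    """

    panel: SnpPanel
    genotypes: np.ndarray  # (n_individuals, n_snps) int8, values 0/1/2
    populations: list[str]
    p_ancestral: np.ndarray
    pop_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    F: dict[str, float] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class AssayEffects:
    """Ground-truth per-SNP effects drawn once per assay.

    ``beta`` has shape (n_snps, n_length_bins); when the assay has a single
    ``bias_sd`` all columns are the same per-SNP draw.  ``efficiency`` is the
    per-SNP enrichment efficiency (mean 1).
    """

    assay: str
    beta: np.ndarray
    efficiency: np.ndarray

    @property
    def per_snp_beta(self) -> np.ndarray:
        return self.beta[:, 0]


@dataclass
class CaptureResult:
    """Everything one simulated capture experiment produced."""

    library: str
    assay: str
    counts: AlleleCounts
    reads: pd.DataFrame  # on/near-target reads: molecule, snp, allele, length, gc
    coverage: np.ndarray  # per-offset base coverage, offsets -W..W
    offsets: np.ndarray
    effects: AssayEffects
    n_on_target_reads: int  # reads overlapping their SNP
    n_background_reads: int  # non-endogenous reads hitting no target


# ---------------------------------------------------------------------- #
# panel and genotypes
# ---------------------------------------------------------------------- #
def _sample_unique_positions(rng, n: int, upper: int) -> np.ndarray:
    """n distinct integers in [1, upper], sorted."""
    if n > upper:
        raise InfeasibleError(f"cannot place {n} SNPs on {upper} positions")
    if n > upper // 2:
        return np.sort(rng.permutation(upper)[:n] + 1)
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.integers(1, upper + 1, size=int(1.2 * (n - out.size)) + 8)
        out = np.unique(np.concatenate([out, draw]))
    return np.sort(rng.permutation(out)[:n])


def simulate_panel(
    n_snps: int,
    n_chromosomes: int = 1,
    chrom_length: int = 50_000_000,
    seed: int = 0,
) -> SnpPanel:
    """Uniformly placed biallelic SNPs on equal-length chromosomes."""
    if n_snps < 0 or n_chromosomes < 1 or chrom_length < 1:
        raise ValidationError("n_snps >= 0, n_chromosomes >= 1, chrom_length >= 1")
    if n_snps > n_chromosomes * chrom_length:
        raise InfeasibleError(
            f"{n_snps} SNPs do not fit on {n_chromosomes} x {chrom_length} bp"
        )
    rng = child_rng(seed, "panel")
    per_chrom = rng.multinomial(n_snps, np.full(n_chromosomes, 1 / n_chromosomes))
    # redistribute overflow if a chromosome was overfilled
    while (per_chrom > chrom_length).any():
        over = per_chrom > chrom_length
        excess = int((per_chrom[over] - chrom_length).sum())
        per_chrom[over] = chrom_length
        room = chrom_length - per_chrom
        give = np.minimum(room, excess)
        for i in np.argsort(-room):
            add = min(int(room[i]), excess)
            per_chrom[i] += add
            excess -= add
            if excess == 0:
                break
        del give
    chroms, positions = [], []
    for c in range(n_chromosomes):
        pos = _sample_unique_positions(rng, int(per_chrom[c]), chrom_length)
        positions.append(pos)
        chroms.append(np.full(pos.size, f"chr{c + 1}"))
    pos = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    chrom = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    pair_idx = rng.integers(0, len(ORDERED_ALLELE_PAIRS), size=pos.size)
    ref = np.array([ORDERED_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([ORDERED_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    width = max(1, len(str(max(n_snps, 1))))
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{i:0{width}d}" for i in range(1, pos.size + 1)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
    )
    # ids assigned after genomic sort so they are in panel order
    return SnpPanel.from_frame(df, sort=True)


def simulate_genotypes(
    panel: SnpPanel,
    n_per_pop: dict[str, int],
    F: dict[str, float] | None = None,
    seed: int = 0,
) -> GenotypeTruth:
    """Balding–Nichols genotypes for one or more populations."""
    if not n_per_pop:
        raise ValidationError("at least one population is required")
    F = dict(F or {})
    for pop, f in F.items():
        if not 0 <= f < 1:
            raise ValidationError(f"drift parameter F for {pop!r} must be in [0, 1)")
    rng = child_rng(seed, "genotypes")
    n_snp = panel.n_snps
    p0 = rng.uniform(0.05, 0.95, size=n_snp)
    genos, labels, pop_freqs = [], [], {}
    for pop, n_ind in n_per_pop.items():
        if n_ind < 0:
            raise ValidationError("individual counts must be >= 0")
        f = F.get(pop, 0.0)
        if f > 0:
            p = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
        else:
            p = p0.copy()
        pop_freqs[pop] = p
        genos.append(rng.binomial(2, p, size=(n_ind, n_snp)).astype(np.int8))
        labels.extend([pop] * n_ind)
    genotypes = (
        np.vstack(genos) if genos else np.empty((0, n_snp), dtype=np.int8)
    )
    return GenotypeTruth(
        panel=panel,
        genotypes=genotypes,
        populations=labels,
        p_ancestral=p0,
        pop_freqs=pop_freqs,
        F={pop: F.get(pop, 0.0) for pop in n_per_pop},
    )


# ---------------------------------------------------------------------- #
# assay effects
# ---------------------------------------------------------------------- #
def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.01 - mean) / sd
    b = (0.99 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_assay_effects(panel: SnpPanel, assay: AssayProfile, seed: int) -> AssayEffects:
    """Per-SNP allelic bias and enrichment efficiency for one assay.

    The random stream is keyed by (seed, assay name) only, so every library
    captured with the same assay under the same master seed shares the same
    per-SNP effects — the reagent, not the library, owns the bias.
    """
    rng = child_rng(seed, "assay-effects", assay.name)
    n = panel.n_snps
    n_bins = len(LENGTH_BIN_LABELS)
    if assay.bias_sd_by_length is not None:
        beta = np.empty((n, n_bins))
        for j, label in enumerate(LENGTH_BIN_LABELS):
            sd = assay.bias_sd_by_length.get(label, assay.bias_sd)
            beta[:, j] = _truncated_normal(rng, assay.bias_mean, sd, n)
    else:
        b = _truncated_normal(rng, assay.bias_mean, assay.bias_sd, n)
        beta = np.tile(np.asarray(b)[:, None], (1, n_bins))
    if assay.efficiency_spread > 0:
        s = assay.efficiency_spread
        efficiency = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)
    else:
        efficiency = np.ones(n)
    return AssayEffects(assay=assay.name, beta=beta, efficiency=efficiency)


# ---------------------------------------------------------------------- #
# capture
# ---------------------------------------------------------------------- #
def simulate_capture(
    truth: GenotypeTruth,
    library: LibraryProfile,
    assay: AssayProfile,
    n_reads: int,
    seed: int = 0,
    rounds: int = 1,
    effects: AssayEffects | None = None,
    efficiency_scale: np.ndarray | None = None,
    max_offset: int = 200,
) -> CaptureResult:
    """Simulate one capture + sequencing experiment.

    Each endogenous molecule carries a target SNP (uniform over the panel),
    a center offset relative to it (uniform in ``[-max_offset, max_offset]``),
    a fragment length (log-normal, floored at 30 bp) and a GC fraction
    (Beta).  Its capture weight is the product of the per-SNP efficiency,
    the logistic length response, the Gaussian GC response and the
    exponential distance decay; ``rounds`` rounds of capture raise the
    weight to the ``rounds`` power.  Reads are drawn with replacement from
    the weighted finite pool of ``library.complexity`` molecules, so
    duplicates arise naturally; a Binomial(n_reads, 1 - endogenous_fraction)
    share of reads is non-endogenous background hitting no target.

    Molecules overlapping their SNP carry an allele: homozygous genotypes
    determine it, and at heterozygous sites the reference allele is drawn
    with probability ``beta_s`` for the molecule's length class.

    ``efficiency_scale`` optionally multiplies the per-SNP capture
    efficiency (used to emulate deliberately down-weighted panel subsets).
    """
    if n_reads < 0:
        raise ValidationError("n_reads must be >= 0")
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    panel = truth.panel
    n_snp = panel.n_snps
    if not 0 <= library.individual < max(truth.n_individuals, 1):
        raise ValidationError(
            f"library {library.name!r} references individual "
            f"{library.individual}, truth has {truth.n_individuals}"
        )
    if effects is None:
        effects = draw_assay_effects(panel, assay, seed)
    rng = child_rng(seed, "capture", library.name, assay.name)
    W = int(max_offset)
    empty = CaptureResult(
        library=library.name,
        assay=assay.name,
        counts=AlleleCounts.from_frame(
            pd.DataFrame(
                columns=[
                    "library",
                    "assay",
                    "snp_id",
                    "ref_count",
                    "alt_count",
                    "other_count",
                    "length_bin",
                    "dedup",
                ]
            )
        ),
        reads=pd.DataFrame(
            columns=["molecule", "snp_id", "length", "gc", "is_ref", "covers", "offset"]
        ),
        coverage=np.zeros(2 * W + 1, dtype=np.int64),
        offsets=np.arange(-W, W + 1),
        effects=effects,
        n_on_target_reads=0,
        n_background_reads=0,
    )
    if n_reads == 0 or n_snp == 0:
        return empty

    # -- molecule pool ------------------------------------------------- #
    complexity = int(library.complexity)
    infinite_pool = complexity > POOL_CAP
    pool = (
        complexity
        if not infinite_pool
        else min(POOL_CAP, max(100_000, 10 * n_reads))
    )
    snp_idx = rng.integers(0, n_snp, size=pool)
    offset = rng.integers(-W, W + 1, size=pool).astype(np.int32)
    length = np.maximum(
        30,
        np.rint(
            rng.lognormal(
                mean=np.log(library.fragment_median),
                sigma=library.fragment_log_sd,
                size=pool,
            )
        ),
    ).astype(np.int32)
    gc = rng.beta(GC_MEAN * GC_CONCENTRATION, (1 - GC_MEAN) * GC_CONCENTRATION, pool)
    start = offset - length // 2
    end = start + length  # molecule covers offsets [start, end)
    covers = (start <= 0) & (end > 0)
    dist = np.maximum(np.maximum(start, 1 - end), 0)

    weight = effects.efficiency[snp_idx].copy()
    if efficiency_scale is not None:
        efficiency_scale = np.asarray(efficiency_scale, dtype=float)
        if efficiency_scale.shape != (n_snp,):
            raise ValidationError("efficiency_scale must have one entry per SNP")
        weight *= efficiency_scale[snp_idx]
    if assay.length_slope != 0:
        weight *= 1.0 / (
            1.0 + np.exp(-assay.length_slope * (length - assay.length_midpoint))
        )
    if assay.gc_curvature != 0:
        weight *= np.exp(-assay.gc_curvature * (gc - assay.gc_optimum) ** 2)
    weight *= np.exp(-dist / assay.offtarget_halfwidth)
    if rounds > 1:
        weight = weight**rounds
    total_weight = weight.sum()
    if not np.isfinite(total_weight) or total_weight <= 0:
        raise ValidationError("degenerate capture weights (all zero or non-finite)")

    geno = truth.genotypes[library.individual, snp_idx]
    bin_idx = assign_length_bin(length)
    beta_m = effects.beta[snp_idx, bin_idx]
    p_ref = np.where(geno == 0, 1.0, np.where(geno == 2, 0.0, beta_m))
    is_ref = rng.random(pool) < p_ref

    # -- read sampling -------------------------------------------------- #
    if library.endogenous_fraction < 1:
        n_background = int(rng.binomial(n_reads, 1.0 - library.endogenous_fraction))
    else:
        n_background = 0
    n_endo = n_reads - n_background
    probs = weight / total_weight
    if infinite_pool:
        attr = rng.choice(pool, size=n_endo, replace=True, p=probs)
        molecule = np.arange(n_endo, dtype=np.int64)  # all reads distinct molecules
        mol_attr = attr
        mol_read_count = np.ones(n_endo, dtype=np.int64)
    else:
        per_molecule = rng.multinomial(n_endo, probs)
        seen = np.nonzero(per_molecule)[0]
        mol_attr = seen
        mol_read_count = per_molecule[seen]
        molecule = np.repeat(seen, mol_read_count)
        attr = molecule  # attribute row per read == molecule id

    # -- counts ---------------------------------------------------------- #
    snp_ids = panel.snp_ids
    n_bins = len(LENGTH_BIN_LABELS)

    def _aggregate(attr_rows, multiplicity):
        """ref/alt counts per (snp, bin) and pooled, for the given molecules."""
        m_cov = covers[attr_rows]
        rows = attr_rows[m_cov]
        mult = multiplicity[m_cov]
        s = snp_idx[rows]
        b = bin_idx[rows]
        r = is_ref[rows]
        key = (s * n_bins + b) * 2 + r
        flat = np.bincount(key, weights=mult, minlength=n_snp * n_bins * 2)
        flat = flat.reshape(n_snp, n_bins, 2).astype(np.int64)
        return flat  # [snp, bin, is_ref]

    pre = _aggregate(mol_attr, mol_read_count)
    post = _aggregate(mol_attr, np.ones_like(mol_read_count))

    frames = []
    for dedup, cube in (("pre", pre), ("post", post)):
        totals = cube.sum(axis=1)  # (n_snp, 2) pooled over bins
        nz = np.nonzero(totals.sum(axis=1))[0]
        frames.append(
            pd.DataFrame(
                {
                    "library": library.name,
                    "assay": assay.name,
                    "snp_id": snp_ids[nz],
                    "ref_count": totals[nz, 1],
                    "alt_count": totals[nz, 0],
                    "other_count": 0,
                    "length_bin": pd.NA,
                    "dedup": dedup,
                }
            )
        )
        for j, label in enumerate(LENGTH_BIN_LABELS):
            nzb = np.nonzero(cube[:, j].sum(axis=1))[0]
            if nzb.size == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "library": library.name,
                        "assay": assay.name,
                        "snp_id": snp_ids[nzb],
                        "ref_count": cube[nzb, j, 1],
                        "alt_count": cube[nzb, j, 0],
                        "other_count": 0,
                        "length_bin": label,
                        "dedup": dedup,
                    }
                )
            )
    counts = AlleleCounts.from_frame(
        pd.concat(frames, ignore_index=True) if frames else empty.counts.df
    )

    # -- coverage track -------------------------------------------------- #
    diff = np.zeros(2 * W + 2, dtype=np.int64)
    rs = np.clip(start[attr], -W, W + 1)
    re = np.clip(end[attr], -W, W + 1)
    inside = rs < re
    np.add.at(diff, rs[inside] + W, 1)
    np.add.at(diff, re[inside] + W, -1)
    coverage = np.cumsum(diff)[: 2 * W + 1]

    reads = pd.DataFrame(
        {
            "molecule": molecule,
            "snp_id": snp_ids[snp_idx[attr]],
            "length": length[attr],
            "gc": gc[attr],
            "is_ref": is_ref[attr],
            "covers": covers[attr],
            "offset": offset[attr],
        }
    )
    return CaptureResult(
        library=library.name,
        assay=assay.name,
        counts=counts,
        reads=reads,
        coverage=coverage,
        offsets=np.arange(-W, W + 1),
        effects=effects,
        n_on_target_reads=int(covers[attr].sum()),
        n_background_reads=n_background,
    )


def simulate_experiment(
    truth: GenotypeTruth,
    libraries: list[LibraryProfile],
    assays: list[AssayProfile],
    n_reads: int,
    seed: int = 0,
    rounds: int = 1,
) -> dict[tuple[str, str], CaptureResult]:
    """Capture every library with every assay; effects drawn once per assay."""
    out = {}
    for assay in assays:
        effects = draw_assay_effects(truth.panel, assay, seed)
        for library in libraries:
            out[(library.name, assay.name)] = simulate_capture(
                truth, library, assay, n_reads, seed=seed, rounds=rounds,
                effects=effects,
            )
    return out


# ---------------------------------------------------------------------- #
# light-weight count-level generators
# ---------------------------------------------------------------------- #
def simulate_read_counts(
    truth: GenotypeTruth,
    assay_name: str,
    beta: np.ndarray | float | None = None,
    mean_depth: float = 5.0,
    seed: int = 0,
    library_names: list[str] | None = None,
    individuals: list[int] | None = None,
    dedup_label: str = "post",
) -> AlleleCounts:
    """Count-level shortcut: Poisson depth, binomial allele sampling.

    Skips the capture mechanics (efficiency, length, GC, duplicates) and
    draws, for each (library, SNP), a Poisson(mean_depth) read total and a
    Binomial reference count with the per-SNP reference-read probability
    implied by the genotype (1 for hom-ref, 0 for hom-alt, ``beta`` at
    heterozygotes; ``beta`` defaults to the unbiased 0.5).  Useful when only
    downstream statistics of the counts matter, e.g. for f4 and filter
    studies at many replicates.
    """
    n_snp = truth.panel.n_snps
    if individuals is None:
        individuals = list(range(truth.n_individuals))
    if library_names is None:
        library_names = [f"L{i + 1}" for i in range(len(individuals))]
    if len(library_names) != len(individuals):
        raise ValidationError("library_names and individuals must align")
    if beta is None:
        beta_arr = np.full(n_snp, 0.5)
    else:
        beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), (n_snp,))
    rng = child_rng(seed, "read-counts", assay_name)
    frames = []
    snp_ids = truth.panel.snp_ids
    for lib, ind in zip(library_names, individuals):
        depth = rng.poisson(mean_depth, size=n_snp)
        g = truth.genotypes[ind]
        p_ref = np.where(g == 0, 1.0, np.where(g == 2, 0.0, beta_arr))
        ref = rng.binomial(depth, p_ref)
        nz = depth > 0
        frames.append(
            pd.DataFrame(
                {
                    "library": lib,
                    "assay": assay_name,
                    "snp_id": snp_ids[nz],
                    "ref_count": ref[nz],
                    "alt_count": depth[nz] - ref[nz],
                    "other_count": 0,
                    "dedup": dedup_label,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(REQUIRED_LIKE))
    )
    return AlleleCounts.from_frame(df)


def simulate_het_counts(
    n_snps: int,
    depth: int,
    bias_mean: float,
    bias_sd: float,
    seed: int = 0,
    assay_name: str = "sim",
) -> tuple[AlleleCounts, np.ndarray]:
    """Reads at known heterozygous sites with a latent per-SNP bias.

    Draws ``beta_s`` from the truncated normal (support [0.01, 0.99]) and a
    Binomial(depth, beta_s) reference count per SNP.  Returns the counts and
    the generating ``beta_s`` for recovery tests.
    """
    if n_snps < 0 or depth < 0:
        raise ValidationError("n_snps and depth must be >= 0")
    rng = child_rng(seed, "het-counts", assay_name)
    beta = _truncated_normal(rng, bias_mean, bias_sd, n_snps)
    k = rng.binomial(depth, beta)
    width = max(1, len(str(max(n_snps, 1))))
    df = pd.DataFrame(
        {
            "library": "L1",
            "assay": assay_name,
            "snp_id": [f"snp{i:0{width}d}" for i in range(1, n_snps + 1)],
            "ref_count": k,
            "alt_count": depth - k,
            "other_count": 0,
        }
    )
    return AlleleCounts.from_frame(df), np.asarray(beta)


REQUIRED_LIKE = (
    "library",
    "assay",
    "snp_id",
    "ref_count",
    "alt_count",
    "other_count",
    "dedup",
)


# ---------------------------------------------------------------------- #
# presets
# ---------------------------------------------------------------------- #
def make_assay_presets() -> dict[str, AssayProfile]:
    """Named profiles emulating the four data-generation platforms.

    The efficiency spreads solve ``Phi((ln 0.1 + s^2/2) / s) = q`` for the
    platform's observed fraction ``q`` of SNPs below 0.1x the mean coverage
    (1%, 5%, 16% and 28% for shotgun-, Twist-, Arbor- and 1240k-like data),
    i.e. the log-normal tail reproduces the coverage-homogeneity contrast.
    Allelic-bias SDs are 0.11, 0.12, 0.18 and 0.15 respectively; GC optima
    sit below the genomic mean for the Arbor-like profile (downward GC
    shift), above it for the 1240k-like profile (upward shift), and near it
    for the Twist-like profile; all enriching profiles prefer longer
    fragments, least so the Twist-like one.  Retrieval is pure: every call
    returns profiles with identical values.
    """
    common = dict(bias_mean=0.52, length_midpoint=50.0)
    return {
        "shotgun-like": AssayProfile(
            name="shotgun-like",
            efficiency_spread=0.8387,
            bias_sd=0.11,
            length_slope=0.0,
            gc_optimum=GC_MEAN,
            gc_curvature=0.0,
            offtarget_halfwidth=1e9,  # no enrichment: flat over the window
            **common,
        ),
        "twist-like": AssayProfile(
            name="twist-like",
            efficiency_spread=1.0590,
            bias_sd=0.12,
            length_slope=0.02,
            gc_optimum=0.38,
            gc_curvature=1.0,
            offtarget_halfwidth=40.0,
            **common,
        ),
        "arbor-like": AssayProfile(
            name="arbor-like",
            efficiency_spread=1.3707,
            bias_sd=0.18,
            length_slope=0.05,
            gc_optimum=0.30,
            gc_curvature=5.0,
            offtarget_halfwidth=40.0,
            **common,
        ),
        "1240k-like": AssayProfile(
            name="1240k-like",
            efficiency_spread=1.6409,
            bias_sd=0.15,
            length_slope=0.06,
            gc_optimum=0.55,
            gc_curvature=7.0,
            offtarget_halfwidth=30.0,
            **common,
        ),
    }
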