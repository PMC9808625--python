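"""The cross-platform SNP compatibility filter.

Different data-generation platforms (shotgun sequencing, different capture
reagents) can favor different alleles at the same SNP, which makes data
sets hard to coanalyze.  At SNPs where an individual is heterozygous, the
rate at which reads match the reference allele can be compared between two
platforms: SNPs where the rates differ are platform-biased.  The filter is
the simple empirical rule of keeping only SNPs where the pooled rates
(over many libraries) differ by less than a threshold (4 percentage points
by default, strict inequality).  Its effect is evaluated by running the f4
symmetry scan before and after restriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import AlleleCounts
from .errors import EmptyInputError, ValidationError
from .fstats import PseudohaploidMatrix, symmetry_scan
from .simulate import GenotypeTruth


@dataclass
class RefMatchTable:
    """Pooled reference-match rates at heterozygous sites, per SNP."""

    df: pd.DataFrame  # snp_id, ref, total, rate
    data_type: str
    min_total: int

    def rates(self) -> pd.Series:
        return self.df.set_index("snp_id")["rate"]


def het_pairs_from_truth(
    truth: GenotypeTruth,
    library_names: list[str],
    individuals: list[int],
) -> pd.DataFrame:
    """(library, snp_id) pairs where the library's individual is heterozygous.

    Synthetic-mode replacement for imputation-based heterozygote posteriors:
    ground-truth genotypes say which sites are heterozygous.
    """
    if len(library_names) != len(individuals):
        raise ValidationError("library_names and individuals must align")
    snp_ids = truth.panel.snp_ids
    frames = []
    for lib, ind in zip(library_names, individuals):
        het = truth.genotypes[ind] == 1
        frames.append(pd.DataFrame({"library": lib, "snp_id": snp_ids[het]}))
    return pd.concat(frames, ignore_index=True)


def refmatch_rates(
    counts: AlleleCounts,
    het: pd.DataFrame,
    min_total: int = 10,
    data_type: str | None = None,
    dedup: str | None = "post",
) -> RefMatchTable:
    """Pool reads across libraries at heterozygous sites; rate per SNP.

    ``het`` is a table of (library, snp_id) pairs at which that library's
    individual is heterozygous (from ground truth, or from an imputation
    posterior > 0.9 on real data).  Counts are summed across libraries per
    SNP; SNPs with fewer than ``min_total`` pooled ref+alt reads are
    omitted, because the empirical rate difference is meaningless at very
    low depth.
    """
    if not {"library", "snp_id"} <= set(het.columns):
        raise ValidationError("het table needs 'library' and 'snp_id' columns")
    sel = counts.select(dedup=dedup)
    if data_type is None:
        assays = sel.assays
        if len(assays) != 1:
            raise ValidationError(
                f"counts hold {len(assays)} assays; pass data_type to select one"
            )
        data_type = assays[0]
    else:
        sel = sel.select(assay=data_type, length_bin="all")
    merged = sel.df.merge(
        het[["library", "snp_id"]].drop_duplicates(),
        on=["library", "snp_id"],
        how="inner",
    )
    pooled = merged.groupby("snp_id")[["ref_count", "alt_count"]].sum()
    total = pooled["ref_count"] + pooled["alt_count"]
    pooled = pooled[total >= min_total]
    total = total[total >= min_total]
    df = pd.DataFrame(
        {
            "snp_id": pooled.index,
            "ref": pooled["ref_count"].to_numpy(),
            "total": total.to_numpy(),
            "rate": pooled["ref_count"].to_numpy() / total.to_numpy(),
        }
    ).reset_index(drop=True)
    return RefMatchTable(df=df, data_type=data_type, min_total=min_total)


def build_filter(
    rates_a: RefMatchTable,
    rates_b: RefMatchTable,
    max_diff: float = 0.04,
    panel=None,
) -> tuple[pd.Series, float]:
    """Flag SNPs whose ref-match rates agree between two data types.

    A SNP passes iff ``|rate_a - rate_b| < max_diff`` (strict inequality);
    SNPs missing a rate in either table fail.  Returns a boolean flag
    indexed by SNP id and the pass fraction.  With a panel, the flag covers
    every panel SNP (and is also attached to it as ``"bias_filter_pass"``);
    otherwise it covers the union of SNPs seen in either table.
    """
    ra = rates_a.rates()
    rb = rates_b.rates()
    shared = ra.index.intersection(rb.index)
    if len(shared) == 0:
        warnings.warn(
            "rate tables share no SNPs; the filter passes nothing", stacklevel=2
        )
    if panel is not None:
        universe = pd.Index(panel.snp_ids)
    else:
        universe = ra.index.union(rb.index)
    diff = (ra.reindex(shared) - rb.reindex(shared)).abs()
    flag = pd.Series(False, index=universe)
    passing = diff.index[diff < max_diff]
    flag.loc[flag.index.intersection(passing)] = True
    pass_fraction = float(flag.mean()) if len(flag) else 0.0
    if panel is not None:
        panel.add_flag("bias_filter_pass", flag.to_numpy())
    return flag, pass_fraction


def evaluate_filter(
    matrix: PseudohaploidMatrix,
    flag: pd.Series | np.ndarray,
    assay_pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], dict]:
    """Symmetry-scan summaries before and after restricting to the filter.

    ``flag`` is either a boolean mask aligned with the matrix SNPs or a
    Series indexed by SNP id (missing ids count as failing).  Per assay
    pair, the ``after`` entry is the scan summary on the passing subset, or
    an ``{"error": ...}`` record when the subset is empty for that pair.
    """
    if isinstance(flag, pd.Series):
        mask = flag.reindex(matrix.snp_ids, fill_value=False).to_numpy(dtype=bool)
    else:
        mask = np.asarray(flag, dtype=bool)
        if mask.shape != matrix.blocks.shape:
            raise ValidationError("filter mask misaligned with matrix SNPs")
    out: dict[tuple[str, str], dict] = {}
    for pair in assay_pairs:
        a, b = pair
        _, before = symmetry_scan(matrix, a, b)
        try:
            _, after = symmetry_scan(matrix, a, b, snp_mask=mask)
        except EmptyInputError as exc:
            after = {"error": str(exc)}
        out[(a, b)] = {"before": before, "after": after}
    return out
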