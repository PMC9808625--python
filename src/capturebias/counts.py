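"""Per-(library, assay, SNP) allele counts.

The central tabular container of the pipeline: one row per combination of
library, assay, SNP and optional stratification keys, holding the number of
sequenced reads matching the reference allele, the alternative allele, or
neither.  Two optional stratifications are understood everywhere:

``dedup``
    ``"pre"`` = all mapped reads (used for enrichment-efficiency metrics),
    ``"post"`` = one read per original library molecule (used for SNP-yield
    metrics and genotype calls).

``length_bin``
    a fragment-length class label such as ``"40-50"``; rows with a null
    ``length_bin`` are the pooled (unstratified) totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .panel import SnpPanel

REQUIRED_COLUMNS = (
    "library",
    "assay",
    "snp_id",
    "ref_count",
    "alt_count",
    "other_count",
)
OPTIONAL_COLUMNS = ("length_bin", "dedup")
COUNT_COLUMNS = ("ref_count", "alt_count", "other_count")
DEDUP_STATES = ("pre", "post")


@dataclass
class AlleleCounts:
    """Validated table of per-SNP allele counts (see module docstring)."""

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleCounts":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"counts table missing columns {missing}")
        keep = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in df.columns]
        df = df.loc[:, keep].reset_index(drop=True)
        for col in COUNT_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"non-numeric value in column {col!r}")
            if (vals < 0).any():
                raise ValidationError(f"negative value in column {col!r}")
            df[col] = vals.astype(np.int64)
        if "dedup" in df.columns:
            bad = ~df["dedup"].isin(DEDUP_STATES) & df["dedup"].notna()
            if bad.any():
                raise ValidationError(
                    f"dedup state must be one of {DEDUP_STATES}, "
                    f"got {df.loc[bad, 'dedup'].iloc[0]!r}"
                )
        return cls(df=df)

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.df)

    @property
    def libraries(self) -> list[str]:
        return sorted(self.df["library"].unique())

    @property
    def assays(self) -> list[str]:
        return sorted(self.df["assay"].unique())

    def select(
        self,
        library: str | None = None,
        assay: str | None = None,
        dedup: str | None = None,
        length_bin: str | None = "pooled",
    ) -> "AlleleCounts":
        """Subset rows.

        ``length_bin`` accepts a bin label, ``"pooled"`` (rows with a null
        bin, the default), or ``"all"`` (no filtering).  Filters on columns
        that are absent from the table are no-ops.
        """
        df = self.df
        if library is not None:
            df = df[df["library"] == library]
        if assay is not None:
            df = df[df["assay"] == assay]
        if dedup is not None and "dedup" in df.columns:
            df = df[df["dedup"] == dedup]
        if "length_bin" in df.columns and length_bin != "all":
            if length_bin == "pooled":
                df = df[df["length_bin"].isna()]
            elif length_bin is not None:
                df = df[df["length_bin"] == length_bin]
        return AlleleCounts(df.reset_index(drop=True))

    def coverage(self, panel: SnpPanel | None = None) -> pd.Series:
        """Total reads (ref+alt+other) per SNP, summed over rows.

        With a panel, the result is reindexed to the full panel (SNPs with
        no counts get coverage 0), in panel order.
        """
        total = (
            self.df[list(COUNT_COLUMNS)].sum(axis=1).groupby(self.df["snp_id"]).sum()
        )
        if panel is not None:
            total = total.reindex(panel.snp_ids, fill_value=0)
        return total

    # ------------------------------------------------------------------ #
    def validate_against_panel(self, panel: SnpPanel) -> None:
        known = set(panel.df["snp_id"])
        unknown = set(self.df["snp_id"]) - known
        if unknown:
            raise ValidationError(
                f"counts reference unknown SNP ids, e.g. {sorted(unknown)[:5]}"
            )

    def check_consistency(self) -> None:
        """Verify the cross-row invariants.

        Post-dedup counts never exceed pre-dedup counts for the same
        (library, assay, SNP, length bin), and length-binned rows sum to the
        pooled row for the same (library, assay, SNP, dedup state).
        """
        df = self.df
        if "dedup" in df.columns and df["dedup"].notna().all():
            keys = ["library", "assay", "snp_id"]
            if "length_bin" in df.columns:
                keys.append("length_bin")
            wide = df.pivot_table(
                index=keys,
                columns="dedup",
                values=list(COUNT_COLUMNS),
                aggfunc="sum",
                fill_value=0,
                dropna=False,
            )
            for col in COUNT_COLUMNS:
                if ("pre" in df["dedup"].values) and ("post" in df["dedup"].values):
                    pre = wide.get((col, "pre"))
                    post = wide.get((col, "post"))
                    if pre is not None and post is not None and (post > pre).any():
                        raise ValidationError(
                            f"post-dedup {col} exceeds pre-dedup for some site"
                        )
        if "length_bin" in df.columns:
            strat = df[df["length_bin"].notna()]
            pooled = df[df["length_bin"].isna()]
            if len(strat) and len(pooled):
                keys = ["library", "assay", "snp_id"]
                if "dedup" in df.columns:
                    keys.append("dedup")
                s = strat.groupby(keys)[list(COUNT_COLUMNS)].sum()
                p = pooled.groupby(keys)[list(COUNT_COLUMNS)].sum()
                joined = s.join(p, how="inner", lsuffix="_strat", rsuffix="_pooled")
                for col in COUNT_COLUMNS:
                    if not (
                        joined[f"{col}_strat"] == joined[f"{col}_pooled"]
                    ).all():
                        raise ValidationError(
                            f"length-binned {col} rows do not sum to pooled total"
                        )
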