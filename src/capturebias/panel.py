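"""The targeted-SNP catalog.

A :class:`SnpPanel` holds one row per targeted SNP (identifier, chromosome,
1-based position, reference and alternative allele), an arbitrary set of
named boolean *flags* marking subsets of the panel (e.g. the core autosomal
set, or the SNPs passing the cross-platform bias filter), and optional
population allele frequencies (alternative-allele frequencies in [0, 1]).

Positions are always stored 1-based; BED input is converted on read.
Panels are sorted by (chromosome, position) on construction so positions are
strictly increasing within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_ALLELES = frozenset("ACGT")

#: Columns every panel frame must carry.
PANEL_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")


@dataclass
class SnpPanel:
    """Targeted SNP catalog with subset flags and population frequencies."""

    df: pd.DataFrame
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    freqs: dict[str, np.ndarray] = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        flags: dict[str, np.ndarray] | None = None,
        freqs: dict[str, np.ndarray] | None = None,
        sort: bool = True,
    ) -> "SnpPanel":
        """Build and validate a panel from a frame with :data:`PANEL_COLUMNS`.

        Flags and frequency arrays must be aligned to the rows of ``df``;
        they are reordered together with the frame when ``sort`` is true.
        """
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"panel frame missing columns {missing}")
        df = df.loc[:, list(PANEL_COLUMNS)].reset_index(drop=True)
        flags = {k: np.asarray(v, dtype=bool) for k, v in (flags or {}).items()}
        freqs = {k: np.asarray(v, dtype=float) for k, v in (freqs or {}).items()}
        if sort and len(df):
            order = np.lexsort(
                (df["pos"].to_numpy(), df["chrom"].astype(str).to_numpy())
            )
            df = df.iloc[order].reset_index(drop=True)
            flags = {k: v[order] for k, v in flags.items()}
            freqs = {k: v[order] for k, v in freqs.items()}
        panel = cls(df=df, flags=flags, freqs=freqs)
        panel.validate()
        return panel

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def index_of(self, snp_ids) -> np.ndarray:
        """Row indices of the given SNP identifiers (error on unknown ids)."""
        idx = pd.Index(self.df["snp_id"]).get_indexer(np.asarray(snp_ids))
        if (idx < 0).any():
            unknown = np.asarray(snp_ids)[idx < 0][:5]
            raise ValidationError(f"unknown SNP identifiers: {list(unknown)} ...")
        return idx

    def flag(self, name: str) -> np.ndarray:
        if name not in self.flags:
            raise ValidationError(f"panel has no flag named {name!r}")
        return self.flags[name]

    def add_flag(self, name: str, mask) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_snps,):
            raise ValidationError(
                f"flag {name!r} has length {mask.size}, panel has {self.n_snps} SNPs"
            )
        self.flags[name] = mask

    def freq(self, population: str) -> np.ndarray:
        if population not in self.freqs:
            raise ValidationError(f"panel has no frequencies for {population!r}")
        return self.freqs[population]

    def maf(self, population: str) -> np.ndarray:
        """Minor-allele frequency for one population."""
        f = self.freq(population)
        return np.minimum(f, 1.0 - f)

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValidationError(f"duplicate SNP identifier {dup!r}")
        if df.duplicated(subset=["chrom", "pos"]).any():
            row = df.loc[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValidationError(
                f"duplicate site {row['chrom']}:{row['pos']} in panel"
            )
        if (df["pos"].to_numpy() < 1).any():
            raise ValidationError("panel positions must be 1-based (>= 1)")
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        has_ref = df["ref"].notna()
        has_alt = df["alt"].notna()
        if (has_ref != has_alt).any():
            raise ValidationError("ref/alt alleles must be both present or both absent")
        both = df.loc[has_ref & has_alt]
        if len(both):
            bad = ~both["ref"].isin(VALID_ALLELES) | ~both["alt"].isin(VALID_ALLELES)
            if bad.any():
                raise ValidationError(
                    f"invalid allele for SNP {both.loc[bad, 'snp_id'].iloc[0]!r}"
                )
            same = both["ref"] == both["alt"]
            if same.any():
                raise ValidationError(
                    f"ref == alt for SNP {both.loc[same, 'snp_id'].iloc[0]!r}"
                )
        for name, arr in self.flags.items():
            if arr.shape != (len(df),):
                raise ValidationError(f"flag {name!r} misaligned with panel")
        for name, arr in self.freqs.items():
            if arr.shape != (len(df),):
                raise ValidationError(f"frequencies {name!r} misaligned with panel")
            finite = arr[np.isfinite(arr)]
            if ((finite < 0) | (finite > 1)).any():
                raise ValidationError(f"frequencies {name!r} outside [0, 1]")
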