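"""Readers and writers for the text formats the pipeline touches.

Supported formats:

* SNP panels as BED (0-based half-open intervals; a SNP at 1-based position
  ``p`` is the interval ``[p-1, p)``) or EIGENSTRAT ``.snp`` (1-based,
  whitespace-delimited: id, chromosome, genetic position, physical position,
  reference allele, alternative allele).
* Allele-count tables as TSV with header columns ``library``, ``assay``,
  ``snp_id``, ``ref_count``, ``alt_count``, ``other_count`` and optional
  ``length_bin`` / ``dedup``.
* Pseudohaploid or diploid genotype matrices as EIGENSTRAT
  ``.geno``/``.snp``/``.ind`` triples (one line per SNP in ``.geno``, one
  character per individual; ``9`` encodes missing and maps to ``-1`` in
  memory).
* Run configuration as YAML (round-trips to an identical document).

Alleles are stored exactly as given; no strand flipping is ever attempted,
because silent flipping would create precisely the allelic biases this
package exists to measure.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import AlleleCounts
from .errors import ParseError, ValidationError
from .panel import SnpPanel

MISSING_GENO = -1  # in-memory missing genotype; 9 on disk


# ---------------------------------------------------------------------- #
# SNP panels
# ---------------------------------------------------------------------- #
def read_panel(path, format: str = "eigenstrat_snp") -> SnpPanel:
    """Read a SNP panel from ``bed`` or ``eigenstrat_snp`` text.

    BED start coordinates are converted to 1-based SNP positions
    (``start + 1``); BED carries no alleles, so ref/alt are left unset.
    """
    path = Path(path)
    rows: list[tuple] = []
    if format == "bed":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 fields", path, lineno)
            try:
                start = int(fields[1])
                int(fields[2])
            except ValueError as exc:
                raise ParseError(f"bad BED coordinate: {exc}", path, lineno) from None
            name = fields[3] if len(fields) > 3 else f"{fields[0]}_{start + 1}"
            rows.append((name, fields[0], start + 1, None, None))
    elif format == "eigenstrat_snp":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(".snp line has fewer than 4 fields", path, lineno)
            try:
                pos = int(fields[3])
            except ValueError as exc:
                raise ParseError(f"bad .snp position: {exc}", path, lineno) from None
            ref = fields[4] if len(fields) > 4 else None
            alt = fields[5] if len(fields) > 5 else None
            rows.append((fields[0], fields[1], pos, ref, alt))
    else:
        raise ValidationError(f"unknown panel format {format!r}")
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return SnpPanel.from_frame(df)


def write_panel(panel: SnpPanel, path, format: str = "eigenstrat_snp") -> None:
    path = Path(path)
    lines = []
    if format == "bed":
        for row in panel.df.itertuples(index=False):
            lines.append(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.snp_id}")
    elif format == "eigenstrat_snp":
        for row in panel.df.itertuples(index=False):
            ref = row.ref if pd.notna(row.ref) else "N"
            alt = row.alt if pd.notna(row.alt) else "N"
            lines.append(
                f"{row.snp_id}\t{row.chrom}\t0.0\t{row.pos}\t{ref}\t{alt}"
            )
    else:
        raise ValidationError(f"unknown panel format {format!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------- #
# allele-count tables
# ---------------------------------------------------------------------- #
def read_counts(path, panel: SnpPanel | None = None) -> AlleleCounts:
    """Read a TSV count table; with a panel, unknown SNP ids are an error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    except pd.errors.EmptyDataError:
        raise ParseError("counts file is empty (no header)", path) from None
    counts = AlleleCounts.from_frame(df)
    if panel is not None:
        counts.validate_against_panel(panel)
    return counts


def write_counts(counts: AlleleCounts, path) -> None:
    counts.df.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------- #
# EIGENSTRAT genotype triples
# ---------------------------------------------------------------------- #
def read_geno(geno_path, snp_path, ind_path):
    """Read an EIGENSTRAT triple.

    Returns ``(matrix, panel, individuals)`` where ``matrix`` is an int8
    array of shape (n_snps, n_individuals) with values in {0, 1, 2} and
    :data:`MISSING_GENO` for missing, and ``individuals`` is a frame with
    columns ``name``, ``sex``, ``population``.
    """
    ind_rows = []
    for lineno, line in enumerate(Path(ind_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(".ind line has fewer than 3 fields", ind_path, lineno)
        ind_rows.append(fields[:3])
    individuals = pd.DataFrame(ind_rows, columns=["name", "sex", "population"])
    panel = read_panel(snp_path, format="eigenstrat_snp")
    n_ind = len(individuals)
    matrix = np.empty((panel.n_snps, n_ind), dtype=np.int8)
    lines = [l for l in Path(geno_path).read_text().splitlines() if l.strip()]
    if len(lines) != panel.n_snps:
        raise ValidationError(
            f".geno has {len(lines)} rows but .snp lists {panel.n_snps} SNPs"
        )
    for i, line in enumerate(lines):
        if len(line) != n_ind:
            raise ValidationError(
                f".geno line {i + 1} has {len(line)} entries "
                f"but .ind lists {n_ind} individuals"
            )
        row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
        if not np.isin(row, (0, 1, 2, 9)).all():
            raise ParseError("genotype codes must be 0/1/2/9", geno_path, i + 1)
        matrix[i] = np.where(row == 9, MISSING_GENO, row)
    return matrix, panel, individuals


def write_geno(matrix, panel: SnpPanel, individuals, prefix) -> None:
    """Write an EIGENSTRAT triple to ``<prefix>.geno/.snp/.ind``.

    Missing entries (negative or 9) are written as ``9``.
    """
    matrix = np.asarray(matrix)
    if matrix.shape[0] != panel.n_snps:
        raise ValidationError("matrix rows do not match panel size")
    if isinstance(individuals, pd.DataFrame):
        ind_df = individuals
    else:
        ind_df = pd.DataFrame(
            {"name": list(individuals), "sex": "U", "population": "pop"}
        )
    if matrix.shape[1] != len(ind_df):
        raise ValidationError("matrix columns do not match individual count")
    prefix = Path(prefix)
    write_panel(panel, prefix.with_suffix(".snp"), format="eigenstrat_snp")
    disk = np.where((matrix < 0) | (matrix > 2), 9, matrix).astype(np.uint8)
    buf = _io.StringIO()
    for row in disk:
        buf.write("".join(chr(ord("0") + v) for v in row))
        buf.write("\n")
    prefix.with_suffix(".geno").write_text(buf.getvalue())
    prefix.with_suffix(".ind").write_text(
        "".join(
            f"{r.name_}\t{r.sex}\t{r.population}\n"
            for r in ind_df.rename(columns={"name": "name_"}).itertuples(index=False)
        )
    )


# ---------------------------------------------------------------------- #
# run configuration
# ---------------------------------------------------------------------- #
@dataclass
class RunConfig:
    """Analysis parameters with defaults matching each module's defaults."""

    seed: int = 0
    panel_path: str | None = None
    counts_path: str | None = None
    geno_prefix: str | None = None
    grid_size: int = 100
    em_max_iter: int = 2000
    em_tol: float = 1e-9
    ascertainment_mode: str = "truncated"
    block_bp: int = 5_000_000
    low_coverage_threshold: float = 0.1
    rel_cov_min: float = 0.5
    maf_min: float = 0.05
    filter_max_diff: float = 0.04
    filter_min_total: int = 10

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
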