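"""Readers, writers and QC for the external formats the pipeline touches.

All genomic intervals use the BED convention throughout the package:
0-based, half-open ``[start, end)``.  Any 1-based source must be converted
at the boundary of this module.  Gene symbols are matched exactly and
case-sensitively; no alias resolution is attempted.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "MutationRecord",
    "GenomicInterval",
    "Linkage",
    "QcReport",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "write_maf",
    "read_intervals",
    "write_intervals",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_mtx",
    "filter_single_cell_matrix",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample identifiers as columns.
    scale
        ``"log2"`` for log-transformed intensities (the default working
        scale of the pipeline) or ``"counts"`` for raw nonnegative integer
        counts (single-cell QC input).
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "counts"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups[:5])}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale == "counts":
            if arr.size and (np.any(arr < 0) or np.any(arr != np.round(arr))):
                raise ValueError("counts-scale matrix must hold nonnegative integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols (order-preserving)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        # emptiness is rejected at the parsing boundary (read_gmt), not here:
        # set algebra (e.g. top-N intersections) may legitimately produce an
        # empty result in memory.
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        return cls(name, tuple(seen))


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene_symbol: str
    variant_classification: str

    def __post_init__(self) -> None:
        if not (self.sample_id and self.gene_symbol and self.variant_classification):
            raise ValueError("mutation record fields must be nonempty")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` with optional strand/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Linkage:
    """A chromatin interaction between two anchors with a read-pair count."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("linkage count must be >= 1")
        if self.anchor_a.chrom == self.anchor_b.chrom and (
            self.anchor_a.start > self.anchor_b.start
        ):
            raise ValueError("anchors on the same chromosome must be ordered by start")


@dataclass
class QcReport:
    """Tallies from single-cell QC filtering; retained+removed = input."""

    n_genes_in: int
    n_cells_in: int
    n_genes_removed_min_cells: int
    n_cells_removed_min_genes: int
    n_cells_removed_max_genes: int
    n_cells_removed_mito: int
    n_genes_out: int
    n_cells_out: int


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT gene-set collection (name, description, genes...).

    Duplicate genes within a line are deduplicated with a logged warning;
    the description column is discarded.  A line with no genes after
    deduplication is a :class:`FormatError` naming the line number.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            genes: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    genes.setdefault(g, None)
            if len(genes) < len([g for g in fields[2:] if g]):
                logger.warning("GMT set %r line %d: duplicate genes dropped", name, lineno)
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, tuple(genes)))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "wt") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def read_maf(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-style tab-delimited mutation table.

    Only ``Hugo_Symbol``, ``Variant_Classification`` and
    ``Tumor_Sample_Barcode`` are consumed; extra columns are ignored and
    ``#``-prefixed lines are skipped.
    """
    with _open_text(path) as fh:
        header: list[str] | None = None
        records: list[MutationRecord] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _MAF_REQUIRED if c not in header]
                if missing:
                    raise FormatError(f"{path}: missing required MAF columns: {missing}")
                idx = {c: header.index(c) for c in _MAF_REQUIRED}
                continue
            records.append(
                MutationRecord(
                    sample_id=fields[idx["Tumor_Sample_Barcode"]],
                    gene_symbol=fields[idx["Hugo_Symbol"]],
                    variant_classification=fields[idx["Variant_Classification"]],
                )
            )
        if header is None:
            raise FormatError(f"{path}: no header line found")
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode\n")
        for r in records:
            fh.write(f"{r.gene_symbol}\t{r.variant_classification}\t{r.sample_id}\n")


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


def _parse_coord(token: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: non-integer coordinate {token!r}") from None


def _make_interval(chrom, start, end, strand=".", name=None, score=None, *, path="", lineno=0):
    if start >= end:
        raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
    return GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)


def read_intervals(path: str | Path, kind: str = "bed") -> list[GenomicInterval] | list[Linkage]:
    """Read a BED (>=3 cols) or BEDPE (>=6 cols, optional 7th count) file.

    Coordinates are interpreted 0-based half-open; strand comes from BED
    column 6 when present, else ``"."``.  The BEDPE count column defaults
    to 1 when absent.
    """
    if kind not in ("bed", "bedpe"):
        raise ValueError(f"kind must be 'bed' or 'bedpe', got {kind!r}")
    out: list = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if kind == "bed":
                if len(f) < 3:
                    raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
                start = _parse_coord(f[1], path, lineno)
                end = _parse_coord(f[2], path, lineno)
                name = f[3] if len(f) > 3 and f[3] != "." else None
                score = None
                if len(f) > 4 and f[4] not in (".", ""):
                    try:
                        score = float(f[4])
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}: non-numeric score {f[4]!r}"
                        ) from None
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                out.append(
                    _make_interval(f[0], start, end, strand, name, score, path=path, lineno=lineno)
                )
            else:
                if len(f) < 6:
                    raise FormatError(f"{path}: line {lineno}: BEDPE needs >=6 columns")
                a = _make_interval(
                    f[0], _parse_coord(f[1], path, lineno), _parse_coord(f[2], path, lineno),
                    path=path, lineno=lineno,
                )
                b = _make_interval(
                    f[3], _parse_coord(f[4], path, lineno), _parse_coord(f[5], path, lineno),
                    path=path, lineno=lineno,
                )
                count = 1
                if len(f) > 6 and f[6] not in (".", ""):
                    count = _parse_coord(f[6], path, lineno)
                if a.chrom == b.chrom and a.start > b.start:
                    a, b = b, a
                out.append(Linkage(a, b, count))
    return out


def write_intervals(items: Sequence[GenomicInterval] | Sequence[Linkage], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for it in items:
            if isinstance(it, Linkage):
                fh.write(
                    f"{it.anchor_a.chrom}\t{it.anchor_a.start}\t{it.anchor_a.end}\t"
                    f"{it.anchor_b.chrom}\t{it.anchor_b.start}\t{it.anchor_b.end}\t{it.count}\n"
                )
            else:
                score = "0" if it.score is None else repr(it.score)
                fh.write(
                    f"{it.chrom}\t{it.start}\t{it.end}\t{it.name or '.'}\t{score}\t{it.strand}\n"
                )


# ---------------------------------------------------------------------------
# Expression TSV / MTX
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_mtx(matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path) -> ExpressionMatrix:
    """Read a MatrixMarket triple (matrix.mtx + genes + barcodes) as counts."""
    from scipy.io import mmread

    m = mmread(str(matrix_path)).toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, -1].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if m.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {m.shape} does not match {len(genes)} genes x {len(barcodes)} barcodes"
        )
    df = pd.DataFrame(m, index=genes, columns=barcodes)
    return ExpressionMatrix(df, scale="counts")


# ---------------------------------------------------------------------------
# Single-cell QC
# ---------------------------------------------------------------------------


def filter_single_cell_matrix(
    counts: ExpressionMatrix,
    min_cells: int = 20,
    min_genes: int = 300,
    max_genes: int = 8000,
    max_mito_frac: float = 0.45,
    mito_prefix: str = "MT-",
) -> tuple[ExpressionMatrix, QcReport]:
    """Apply the single-cell QC filters in one fixed pass.

    Genes detected (count > 0) in fewer than ``min_cells`` cells are removed
    first.  Then — on the gene-filtered matrix — cells expressing fewer than
    ``min_genes`` or more than ``max_genes`` genes, or whose mitochondrial
    count fraction exceeds ``max_mito_frac``, are removed.  Mitochondrial
    genes are identified by symbol prefix.  Strictly one pass, no iteration.
    """
    if counts.scale != "counts":
        raise ValueError("single-cell QC expects a counts-scale matrix")
    vals = counts.values
    n_genes_in, n_cells_in = vals.shape

    detected = vals > 0
    gene_keep = detected.sum(axis=1) >= min_cells
    vals_g = vals.loc[gene_keep]
    n_genes_removed = int((~gene_keep).sum())

    detected_g = vals_g > 0
    genes_per_cell = detected_g.sum(axis=0)
    mito_mask = vals_g.index.str.startswith(mito_prefix)
    totals = vals_g.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = vals_g.loc[mito_mask].sum(axis=0) / totals
    mito_frac = mito_frac.fillna(0.0)

    too_few = genes_per_cell < min_genes
    too_many = genes_per_cell > max_genes
    too_mito = mito_frac > max_mito_frac

    cell_keep = ~(too_few | too_many | too_mito)
    # attribute each removed cell to the first rule that fires, in filter order
    removed_min = too_few
    removed_max = too_many & ~too_few
    removed_mito = too_mito & ~too_few & ~too_many

    out_vals = vals_g.loc[:, cell_keep]
    if out_vals.shape[1] == 0:
        raise ValueError("all cells removed by QC filters")

    report = QcReport(
        n_genes_in=n_genes_in,
        n_cells_in=n_cells_in,
        n_genes_removed_min_cells=n_genes_removed,
        n_cells_removed_min_genes=int(removed_min.sum()),
        n_cells_removed_max_genes=int(removed_max.sum()),
        n_cells_removed_mito=int(removed_mito.sum()),
        n_genes_out=out_vals.shape[0],
        n_cells_out=out_vals.shape[1],
    )
    return ExpressionMatrix(out_vals, scale="counts"), report
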