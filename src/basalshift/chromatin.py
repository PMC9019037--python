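"""Insulated-neighborhood boundary calling and chromatin-loop assembly.

A CTCF peak is promoted to a putative insulated-neighborhood boundary
when it is co-occupied by at least ``min_cohesin`` of the supplied
cohesin subunit tracks (RAD21 / STAG1 / SMC1A).  Linkages (e.g. from
ChIA-PET) whose two anchors land on two distinct boundaries become
loops; a loop is *convergent* when the left boundary's CTCF motif is on
the "+" strand and the right one's on "-", and *strong* when its summed
linkage count exceeds 3 read pairs.

Peak-to-gene annotation follows the promoter/flank convention: a peak
midpoint within +/-3 kb of the nearest TSS is a promoter assignment,
within +/-50 kb a flank assignment, otherwise none.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, Linkage

__all__ = [
    "Boundary",
    "Loop",
    "PeakGeneAssignment",
    "call_boundaries",
    "assemble_loops",
    "annotate_peaks_to_genes",
    "gain_of_function_sites",
]


@dataclass(frozen=True)
class Boundary:
    interval: GenomicInterval
    motif_strand: str  # "+", "-", or "unknown"
    supporting_factors: tuple[str, ...]

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.interval.chrom, self.interval.start, self.interval.end)


@dataclass(frozen=True)
class Loop:
    left: Boundary
    right: Boundary
    linkage_count: int
    convergent: bool
    strong: bool

    def __post_init__(self) -> None:
        if self.left.interval.chrom != self.right.interval.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.left.interval.start >= self.right.interval.start:
            raise ValueError("left boundary must precede right boundary")


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: GenomicInterval
    gene: str | None
    relation: str  # "promoter", "flank", "none"
    distance: int | None  # signed bp, positive downstream of transcription


def _trees(intervals: list[GenomicInterval], pad: int = 0) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        by_chrom[iv.chrom].addi(iv.start - pad, iv.end + pad, iv)
    return by_chrom


def call_boundaries(
    ctcf_peaks: list[GenomicInterval],
    cohesin_tracks: dict[str, list[GenomicInterval]],
    motif_intervals: list[GenomicInterval],
    window: int = 0,
    min_cohesin: int = 2,
) -> list[Boundary]:
    """Promote cohesin-co-occupied CTCF peaks to boundaries.

    A CTCF peak becomes a boundary when peaks from at least ``min_cohesin``
    of the supplied cohesin tracks overlap it (all intervals expanded by
    ``window`` bp on each side before the overlap test).  The motif strand
    is taken from the unique overlapping motif, else ``"unknown"``.
    """
    if min_cohesin > len(cohesin_tracks):
        raise ValueError(
            f"min_cohesin={min_cohesin} exceeds the {len(cohesin_tracks)} supplied tracks"
        )
    cohesin_trees = {name: _trees(track, pad=window) for name, track in cohesin_tracks.items()}
    motif_trees = _trees(motif_intervals)

    boundaries: list[Boundary] = []
    for peak in ctcf_peaks:
        lo, hi = peak.start - window, peak.end + window
        support = tuple(
            name
            for name, trees in cohesin_trees.items()
            if peak.chrom in trees and trees[peak.chrom].overlap(lo, hi)
        )
        if len(support) < min_cohesin:
            continue
        strand = "unknown"
        if peak.chrom in motif_trees:
            hits = [h.data for h in motif_trees[peak.chrom].overlap(peak.start, peak.end)]
            if len(hits) == 1:
                strand = hits[0].strand if hits[0].strand in ("+", "-") else "unknown"
        boundaries.append(Boundary(peak, strand, support))
    return boundaries


def assemble_loops(
    boundaries: list[Boundary],
    linkages: list[Linkage],
    min_linkages_strong: int = 4,
) -> list[Loop]:
    """Turn linkages whose anchors hit two distinct boundaries into loops.

    Linkage counts landing on the same ordered boundary pair are summed.
    A loop is flagged strong when its summed count reaches
    ``min_linkages_strong`` (default 4, i.e. strictly more than 3 read
    pairs), and convergent when the left boundary carries a "+" motif and
    the right a "-" motif.
    """
    btrees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for b in boundaries:
        btrees[b.interval.chrom].addi(b.interval.start, b.interval.end, b)

    pair_counts: dict[tuple, int] = defaultdict(int)
    pair_objs: dict[tuple, tuple[Boundary, Boundary]] = {}
    for lk in linkages:
        hits_a = {
            h.data for h in btrees.get(lk.anchor_a.chrom, IntervalTree()).overlap(
                lk.anchor_a.start, lk.anchor_a.end
            )
        }
        hits_b = {
            h.data for h in btrees.get(lk.anchor_b.chrom, IntervalTree()).overlap(
                lk.anchor_b.start, lk.anchor_b.end
            )
        }
        for ba in hits_a:
            for bb in hits_b:
                if ba.key == bb.key:
                    continue
                left, right = sorted((ba, bb), key=lambda b: (b.interval.chrom, b.interval.start))
                key = (left.key, right.key)
                pair_counts[key] += lk.count
                pair_objs[key] = (left, right)

    return [
        Loop(
            left,
            right,
            pair_counts[key],
            convergent=(left.motif_strand == "+" and right.motif_strand == "-"),
            strong=pair_counts[key] >= min_linkages_strong,
        )
        for key, (left, right) in sorted(pair_objs.items())
    ]


def annotate_peaks_to_genes(
    peaks: list[GenomicInterval],
    tss_table: pd.DataFrame,
    promoter_bp: int = 3000,
    flank_bp: int = 50000,
) -> list[PeakGeneAssignment]:
    """Nearest-TSS annotation of peaks with promoter/flank classification.

    ``tss_table`` needs columns ``gene, chrom, pos, strand``.  Distance is
    the signed bp from peak midpoint to the TSS, strand-aware so that
    positive means downstream of transcription.  Equidistant TSS ties break
    by lexicographic gene id.  Relation: promoter when |d| <= promoter_bp,
    flank when promoter_bp < |d| <= flank_bp, else none (gene still
    reported as the nearest).
    """
    for col in ("gene", "chrom", "pos", "strand"):
        if col not in tss_table.columns:
            raise KeyError(f"tss_table lacks required column {col!r}")
    by_chrom = {
        chrom: grp.sort_values(["pos", "gene"]).reset_index(drop=True)
        for chrom, grp in tss_table.groupby("chrom")
    }
    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        grp = by_chrom.get(peak.chrom)
        if grp is None or grp.empty:
            out.append(PeakGeneAssignment(peak, None, "none", None))
            continue
        mid = peak.midpoint
        dist_abs = (grp["pos"] - mid).abs()
        best = dist_abs.min()
        cands = grp[dist_abs == best].sort_values("gene")
        row = cands.iloc[0]
        signed = mid - int(row["pos"])
        if row["strand"] == "-":
            signed = -signed
        if abs(signed) <= promoter_bp:
            relation = "promoter"
        elif abs(signed) <= flank_bp:
            relation = "flank"
        else:
            relation = "none"
        out.append(PeakGeneAssignment(peak, str(row["gene"]), relation, int(signed)))
    return out


def gain_of_function_sites(
    mutant_peaks: list[GenomicInterval],
    reference_peaks: list[GenomicInterval],
) -> tuple[list[GenomicInterval], float]:
    """Mutant peaks with zero base-pair overlap with any reference peak,
    plus their fraction of the mutant set."""
    if not mutant_peaks:
        raise ValueError("mutant peak set is empty")
    ref_trees = _trees(reference_peaks)
    subset = [
        p
        for p in mutant_peaks
        if p.chrom not in ref_trees or not ref_trees[p.chrom].overlap(p.start, p.end)
    ]
    return subset, len(subset) / len(mutant_peaks)
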