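"""Boundary calling, loop assembly, peak annotation and gain-of-function logic."""

import numpy as np
import pandas as pd
import pytest

from basalshift.chromatin import (
    Boundary,
    annotate_peaks_to_genes,
    assemble_loops,
    call_boundaries,
    gain_of_function_sites,
)
from basalshift.io_formats import GenomicInterval, Linkage
from basalshift.synthetic_data import SimulationConfig, simulate_chromatin_tracks
from _oracles import brute_boundaries, intervals_overlap


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand=strand)


def random_tracks(rng, n=100, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, 100_000))
        out.append(iv(c, s, s + int(rng.integers(50, 500))))
    return out


class TestCallBoundaries:
    def test_two_of_three_support(self):
        ctcf = [iv("chr1", 100, 200)]
        tracks = {
            "RAD21": [iv("chr1", 150, 250)],
            "STAG1": [iv("chr1", 120, 180)],
            "SMC1A": [],
        }
        (b,) = call_boundaries(ctcf, tracks, [])
        assert set(b.supporting_factors) == {"RAD21", "STAG1"}
        assert b.motif_strand == "unknown"

    def test_no_cohesin_no_boundary(self):
        ctcf = [iv("chr1", 100, 200)]
        tracks = {"RAD21": [iv("chr1", 300, 400)], "STAG1": [], "SMC1A": []}
        assert call_boundaries(ctcf, tracks, []) == []

    def test_unique_motif_sets_strand(self):
        ctcf = [iv("chr1", 100, 200)]
        tracks = {"RAD21": [iv("chr1", 100, 200)], "STAG1": [iv("chr1", 100, 200)]}
        motifs = [iv("chr1", 150, 170, "+")]
        (b,) = call_boundaries(ctcf, tracks, motifs)
        assert b.motif_strand == "+"

    def test_ambiguous_motifs_unknown(self):
        ctcf = [iv("chr1", 100, 200)]
        tracks = {"RAD21": [iv("chr1", 100, 200)], "STAG1": [iv("chr1", 100, 200)]}
        motifs = [iv("chr1", 110, 120, "+"), iv("chr1", 150, 160, "-")]
        (b,) = call_boundaries(ctcf, tracks, motifs)
        assert b.motif_strand == "unknown"

    def test_min_cohesin_exceeds_tracks_is_config_error(self):
        with pytest.raises(ValueError, match="min_cohesin"):
            call_boundaries([], {"RAD21": []}, [], min_cohesin=2)

    @pytest.mark.parametrize("window", [0, 25])
    def test_matches_quadratic_oracle(self, rng, window):
        ctcf = random_tracks(rng, 150)
        tracks = {name: random_tracks(rng, 120) for name in ("RAD21", "STAG1", "SMC1A")}
        motifs = [
            iv(p.chrom, p.start + 5, p.start + 25, "+" if rng.random() < 0.5 else "-")
            for p in random_tracks(rng, 80)
        ]
        mine = call_boundaries(ctcf, tracks, motifs, window=window)
        got = [((b.interval.chrom, b.interval.start, b.interval.end), b.motif_strand,
                tuple(sorted(b.supporting_factors))) for b in mine]
        oracle = [(k, s, tuple(sorted(sup)))
                  for k, s, sup in brute_boundaries(ctcf, tracks, motifs, window=window)]
        assert got == oracle


def boundary(chrom, start, end, strand):
    return Boundary(iv(chrom, start, end), strand, ("RAD21", "STAG1"))


class TestAssembleLoops:
    def make_pair(self, strand_l="+", strand_r="-"):
        left = boundary("chr1", 1000, 1400, strand_l)
        right = boundary("chr1", 9000, 9400, strand_r)
        return left, right

    def link(self, count):
        return Linkage(iv("chr1", 900, 1500), iv("chr1", 8900, 9500), count)

    def test_strong_convergent_loop(self):
        left, right = self.make_pair()
        (loop,) = assemble_loops([left, right], [self.link(5)])
        assert loop.strong and loop.convergent and loop.linkage_count == 5

    def test_count_three_is_not_strong(self):
        left, right = self.make_pair()
        (loop,) = assemble_loops([left, right], [self.link(3)])
        assert not loop.strong

    def test_divergent_orientation_not_convergent(self):
        left, right = self.make_pair("-", "+")
        (loop,) = assemble_loops([left, right], [self.link(5)])
        assert not loop.convergent

    def test_counts_summed_over_repeated_linkages(self):
        left, right = self.make_pair()
        loops = assemble_loops([left, right], [self.link(2), self.link(2)])
        assert loops[0].linkage_count == 4 and loops[0].strong

    def test_anchor_missing_boundary_yields_no_loop(self):
        left, _ = self.make_pair()
        assert assemble_loops([left], [self.link(5)]) == []

    def test_every_loop_anchored_on_called_boundaries(self, rng):
        bounds = [boundary("chr1", s, s + 200, "+") for s in range(0, 20_000, 2000)]
        links = []
        for a, b in rng.integers(0, 19_000, size=(30, 2)):
            lo, hi = int(min(a, b)), int(max(a, b))
            if hi - lo > 500:
                links.append(Linkage(iv("chr1", lo, lo + 300), iv("chr1", hi, hi + 300), 4))
        loops = assemble_loops(bounds, links)
        keys = {b.key for b in bounds}
        for l in loops:
            assert l.left.key in keys and l.right.key in keys
            assert l.strong == (l.linkage_count > 3)


class TestAnnotatePeaks:
    TSS = pd.DataFrame(
        [{"gene": "GENE1", "chrom": "chr1", "pos": 10_000, "strand": "+"}]
    )

    def annotate_midpoint(self, mid):
        peak = iv("chr1", mid - 50, mid + 50)
        (a,) = annotate_peaks_to_genes([peak], self.TSS)
        return a

    def test_promoter_within_3kb(self):
        a = self.annotate_midpoint(12_000)
        assert a.relation == "promoter" and a.distance == 2000

    def test_flank_within_50kb(self):
        a = self.annotate_midpoint(55_000)
        assert a.relation == "flank" and a.distance == 45_000

    def test_beyond_flank_is_none(self):
        a = self.annotate_midpoint(70_001)
        assert a.relation == "none"

    def test_strand_aware_sign(self):
        tss = pd.DataFrame([{"gene": "G", "chrom": "chr1", "pos": 10_000, "strand": "-"}])
        peak = iv("chr1", 11_950, 12_050)  # midpoint 12_000, upstream on '-' gene
        (a,) = annotate_peaks_to_genes([peak], tss)
        assert a.distance == -2000 and a.relation == "promoter"

    def test_equidistant_tie_lexicographic(self):
        tss = pd.DataFrame(
            [
                {"gene": "B", "chrom": "chr1", "pos": 9_000, "strand": "+"},
                {"gene": "A", "chrom": "chr1", "pos": 11_000, "strand": "+"},
            ]
        )
        (a,) = annotate_peaks_to_genes([iv("chr1", 9_950, 10_050)], tss)
        assert a.gene == "A"

    def test_nearest_tss_wins(self):
        tss = pd.DataFrame(
            [
                {"gene": "NEAR", "chrom": "chr1", "pos": 10_000, "strand": "+"},
                {"gene": "FAR", "chrom": "chr1", "pos": 40_000, "strand": "+"},
            ]
        )
        (a,) = annotate_peaks_to_genes([iv("chr1", 11_950, 12_050)], tss)
        assert a.gene == "NEAR"


class TestGainOfFunction:
    def test_partial_overlap(self):
        mutant = [iv("chr1", 0, 100), iv("chr1", 500, 600), iv("chr2", 0, 100)]
        reference = [iv("chr1", 50, 80)]
        subset, frac = gain_of_function_sites(mutant, reference)
        assert len(subset) == 2 and frac == pytest.approx(2 / 3)

    def test_full_overlap_fraction_zero(self):
        mutant = [iv("chr1", 0, 100)]
        subset, frac = gain_of_function_sites(mutant, [iv("chr1", 0, 100)])
        assert subset == [] and frac == 0.0

    def test_empty_mutant_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            gain_of_function_sites([], [iv("chr1", 0, 10)])

    def test_matches_brute_force_overlap(self, rng):
        mutant = random_tracks(rng, 200)
        reference = random_tracks(rng, 200)
        subset, frac = gain_of_function_sites(mutant, reference)
        oracle = [p for p in mutant if not any(intervals_overlap(p, r) for r in reference)]
        assert [(p.chrom, p.start, p.end) for p in subset] == [
            (p.chrom, p.start, p.end) for p in oracle
        ]


class TestPlantedRecovery:
    def test_boundaries_and_loops_recovered_exactly(self, small_config):
        tracks, motifs, linkages, tss, truth = simulate_chromatin_tracks(small_config)
        cohesin = {k: tracks[k] for k in ("RAD21", "STAG1", "SMC1A")}
        bounds = call_boundaries(tracks["CTCF"], cohesin, motifs)
        called = {b.key for b in bounds}
        assert called == set(truth.boundary_keys)  # precision = recall = 1
        assert called.isdisjoint(truth.decoy_keys)

        loops = assemble_loops(bounds, linkages)
        strong_convergent = {
            (l.left.key, l.right.key, l.linkage_count)
            for l in loops
            if l.strong and l.convergent
        }
        assert strong_convergent == set(truth.convergent_loops)
        weak = {(l.left.key, l.right.key) for l in loops if not l.strong}
        assert weak == {(a, b) for a, b, _ in truth.nonconvergent_loops}

    def test_inside_tss_fall_within_loop_spans(self, small_config):
        tracks, motifs, linkages, tss, truth = simulate_chromatin_tracks(small_config)
        spans = {
            (left[0], left[1], right[2]) for left, right, _ in truth.convergent_loops
        }
        inside = tss[tss["gene"].isin(truth.tss_inside)]
        for _, row in inside.iterrows():
            assert any(c == row["chrom"] and s <= row["pos"] < e for c, s, e in spans)
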