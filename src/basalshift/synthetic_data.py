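"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration (including the
seed): the same config yields byte-identical output.  Alongside each data
set a ground-truth object records which genes carry the planted programs
and which samples carry which labels, so downstream recovery tests never
re-derive generator internals.

Bulk expression is simulated as Gaussian log2 intensities (all downstream
statistics are rank-based or operate on the log scale); raw counts are
produced only for the single-cell QC fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GenomicInterval,
    Linkage,
    MutationRecord,
)
from .immune_tmb import NON_TRUNCATING_CLASSES, TRUNCATING_CLASSES

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "ChromatinTruth",
    "DEFAULT_SEED",
    "BCK_GENES",
    "simulate_cell_line_panel",
    "simulate_paired_cohort",
    "simulate_survival_cohort",
    "simulate_maf",
    "simulate_chromatin_tracks",
    "simulate_single_cell_counts",
]

#: Default seed shipped with the package for reproducible runs.
DEFAULT_SEED = 20220419

#: The six basal cytokeratins; the planted basal program starts with these
#: symbols so that the default BCK scorer finds them in simulated data.
BCK_GENES = ("KRT5", "KRT6A", "KRT6B", "KRT14", "KRT16", "KRT17")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the cohort sizes and planted
    effects of the emulated design as defaults.

    ``basal_shift_log2`` is the log2 up-shift planted on basal-program genes
    in mutant metastases (and on class-marker genes in the cell-line panel).
    ``immune_coupling`` scales how strongly immune-program genes track a
    sample's realized basal elevation.  ``pairing_sd`` is the SD of the
    per-patient random effect shared by the two lesions of a pair;
    ``basal_activity_sd`` (default 0: the planted contrast is the only
    basal-program signal) adds a per-sample latent basal activity; switch
    it on for quartile-stratification designs, where cross-sample
    heterogeneity of the basal program is the object of study.
    """

    seed: int = DEFAULT_SEED
    n_genes: int = 1000
    n_basal_genes: int = 75
    n_luminal_genes: int = 68
    n_immune_genes: int = 141
    n_luminal_lines: int = 33
    n_basal_lines: int = 39
    n_wt_patients: int = 44
    n_mut_patients: int = 7
    basal_shift_log2: float = 2.0
    immune_coupling: float = 0.8
    noise_sd: float = 1.0
    pairing_sd: float = 1.0
    basal_activity_sd: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    hazard_ratio_bck_high: float = 2.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.025
    mutation_rate_truncating: float = 3.0
    mutation_rate_non_truncating: float = 4.0
    mutation_rate_silent: float = 1.0
    n_boundary_pairs: int = 5
    linkage_count: int = 5
    n_decoy_ctcf: int = 10
    n_nonconvergent_pairs: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_basal_genes", "n_luminal_genes", "n_immune_genes",
            "n_luminal_lines", "n_basal_lines", "n_wt_patients", "n_mut_patients",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_basal_genes + self.n_luminal_genes + self.n_immune_genes > self.n_genes:
            raise ValueError("planted gene programs exceed n_genes")
        if self.basal_shift_log2 < 0:
            raise ValueError("basal_shift_log2 must be >= 0")
        if not 0 <= self.immune_coupling <= 1:
            raise ValueError("immune_coupling must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.pairing_sd < 0:
            raise ValueError("pairing_sd must be >= 0")
        if self.hazard_ratio_bck_high <= 0:
            raise ValueError("hazard_ratio_bck_high must be > 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth of an expression simulation."""

    basal_gene_ids: tuple[str, ...]
    luminal_gene_ids: tuple[str, ...]
    immune_gene_ids: tuple[str, ...]
    sample_annotations: pd.DataFrame
    effects: dict = field(default_factory=dict)

    def basal_set(self, name: str = "planted_basal") -> GeneSet:
        return GeneSet(name, self.basal_gene_ids)

    def luminal_set(self, name: str = "planted_luminal") -> GeneSet:
        return GeneSet(name, self.luminal_gene_ids)

    def immune_set(self, name: str = "planted_immune") -> GeneSet:
        return GeneSet(name, self.immune_gene_ids)

    def bck_set(self) -> GeneSet:
        """The six-gene basal-cytokeratin subset of the planted basal program."""
        present = tuple(g for g in BCK_GENES if g in self.basal_gene_ids)
        return GeneSet("BCK", present)


def _gene_ids(config: SimulationConfig) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], list[str]]:
    nb, nl, ni = config.n_basal_genes, config.n_luminal_genes, config.n_immune_genes
    basal = tuple(BCK_GENES[: min(6, nb)]) + tuple(
        f"BASAL{i:04d}" for i in range(1, nb - min(6, nb) + 1)
    )
    luminal = tuple(f"LUM{i:04d}" for i in range(1, nl + 1))
    immune = tuple(f"IMM{i:04d}" for i in range(1, ni + 1))
    n_bg = config.n_genes - nb - nl - ni
    background = [f"GENE{i:05d}" for i in range(1, n_bg + 1)]
    all_genes = list(basal) + list(luminal) + list(immune) + background
    return basal, luminal, immune, all_genes


def _baselines(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    return rng.normal(config.baseline_mean, config.baseline_sd, size=n)


def simulate_cell_line_panel(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """A labeled luminal/basal cell-line reference panel.

    Basal-program genes are shifted up by ``basal_shift_log2`` in basal
    lines and luminal-program genes in luminal lines, on top of per-gene
    baselines and iid Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    basal_g, luminal_g, immune_g, genes = _gene_ids(config)
    n_lines = config.n_luminal_lines + config.n_basal_lines
    samples = [f"LuminalLine{i:02d}" for i in range(1, config.n_luminal_lines + 1)] + [
        f"BasalLine{i:02d}" for i in range(1, config.n_basal_lines + 1)
    ]
    classes = ["luminal"] * config.n_luminal_lines + ["basal"] * config.n_basal_lines

    base = _baselines(rng, config, len(genes))
    vals = base[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n_lines))

    gene_index = pd.Index(genes)
    basal_rows = gene_index.get_indexer(list(basal_g))
    luminal_rows = gene_index.get_indexer(list(luminal_g))
    is_basal = np.array([c == "basal" for c in classes])
    vals[np.ix_(basal_rows, np.where(is_basal)[0])] += config.basal_shift_log2
    vals[np.ix_(luminal_rows, np.where(~is_basal)[0])] += config.basal_shift_log2

    matrix = ExpressionMatrix(pd.DataFrame(vals, index=gene_index, columns=samples))
    ann = pd.DataFrame({"sample_id": samples, "class": classes}).set_index("sample_id")
    truth = PlantedTruth(
        basal_gene_ids=basal_g,
        luminal_gene_ids=luminal_g,
        immune_gene_ids=immune_g,
        sample_annotations=ann,
        effects={"class_shift_log2": config.basal_shift_log2},
    )
    return matrix, truth


def simulate_paired_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """A paired primary-metastasis ER+ cohort with WT and mutant patients.

    Each patient contributes a primary and a metastatic sample sharing a
    per-patient, per-gene Gaussian random effect (SD ``pairing_sd``).  Each
    sample carries a latent basal activity ``a ~ N(0, basal_activity_sd)``;
    mutant metastases get an extra ``+basal_shift_log2``.  Basal-program
    genes are elevated by ``a``; immune-program genes by
    ``immune_coupling * a``.  Survival times are exponential with the hazard
    multiplied by ``hazard_ratio_bck_high`` for samples in the top quartile
    of latent basal activity, with independent exponential censoring.

    Returns ``(matrix, annotations, survival, truth)`` where annotations has
    one row per sample (patient_id, lesion, genotype) and survival one row
    per sample (time, event).
    """
    if config.n_wt_patients + config.n_mut_patients < 4:
        raise ValueError("need at least 4 patients (quartiles undefined downstream)")
    rng = np.random.default_rng(config.seed)
    basal_g, luminal_g, immune_g, genes = _gene_ids(config)
    gene_index = pd.Index(genes)

    patients = [f"WT{i:03d}" for i in range(1, config.n_wt_patients + 1)] + [
        f"MUT{i:03d}" for i in range(1, config.n_mut_patients + 1)
    ]
    genotypes = ["WT"] * config.n_wt_patients + ["mutant"] * config.n_mut_patients

    sample_ids: list[str] = []
    rows = []
    for pat, gt in zip(patients, genotypes):
        for lesion in ("primary", "metastasis"):
            sid = f"{pat}_{'PRI' if lesion == 'primary' else 'MET'}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "patient_id": pat, "lesion": lesion, "genotype": gt})
    ann = pd.DataFrame(rows).set_index("sample_id")

    p, n = len(genes), len(sample_ids)
    base = _baselines(rng, config, p)
    vals = base[:, None] + rng.normal(0.0, config.noise_sd, size=(p, n))

    # shared patient effect: each pair of columns gets the same per-gene draw
    patient_effect = rng.normal(0.0, config.pairing_sd, size=(p, len(patients)))
    vals += np.repeat(patient_effect, 2, axis=1)

    activity = rng.normal(0.0, config.basal_activity_sd, size=n)
    is_mut_met = np.array(
        [(r["genotype"] == "mutant" and r["lesion"] == "metastasis") for r in rows]
    )
    activity = activity + np.where(is_mut_met, config.basal_shift_log2, 0.0)

    basal_rows = gene_index.get_indexer(list(basal_g))
    immune_rows = gene_index.get_indexer(list(immune_g))
    vals[basal_rows, :] += activity[None, :]
    vals[immune_rows, :] += config.immune_coupling * activity[None, :]

    matrix = ExpressionMatrix(pd.DataFrame(vals, index=gene_index, columns=sample_ids))

    # survival driven by latent basal activity: top quartile (by rank, so
    # the group is well defined even when activities tie) gets the elevated hazard
    k = max(1, int(np.ceil(n / 4)))
    bck_high = np.zeros(n, dtype=bool)
    bck_high[np.argsort(-activity, kind="stable")[:k]] = True
    hazard = config.baseline_hazard * np.where(bck_high, config.hazard_ratio_bck_high, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"sample_id": sample_ids, "time": time, "event": event, "bck_high": bck_high}
    ).set_index("sample_id")

    ann = ann.assign(basal_activity=activity)
    truth = PlantedTruth(
        basal_gene_ids=basal_g,
        luminal_gene_ids=luminal_g,
        immune_gene_ids=immune_g,
        sample_annotations=ann,
        effects={
            "basal_shift_log2": config.basal_shift_log2,
            "immune_coupling": config.immune_coupling,
            "hazard_ratio_bck_high": config.hazard_ratio_bck_high,
        },
    )
    return matrix, ann, survival, truth


def simulate_survival_cohort(
    n: int,
    hazard_ratio: float,
    seed: int,
    baseline_hazard: float = 0.1,
    censoring_rate: float = 0.0,
) -> pd.DataFrame:
    """Two balanced groups with exponential event times; group 1's hazard is
    multiplied by ``hazard_ratio``.  Used for survival-model calibration."""
    rng = np.random.default_rng(seed)
    group = np.zeros(n, dtype=int)
    group[n // 2 :] = 1
    hazard = baseline_hazard * np.where(group == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"sample_id": [f"S{i:04d}" for i in range(n)], "time": time, "event": event, "group": group}
    ).set_index("sample_id")


def simulate_maf(
    config: SimulationConfig,
    sample_ids: Sequence[str] | None = None,
    n_samples: int = 100,
) -> list[MutationRecord]:
    """Per-sample mutation tables with Poisson-distributed truncating,
    non-truncating and (excluded-class) Silent rows."""
    rng = np.random.default_rng(config.seed)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    _, _, _, genes = _gene_ids(config)
    records: list[MutationRecord] = []
    for sid in sample_ids:
        k_t = rng.poisson(config.mutation_rate_truncating)
        k_n = rng.poisson(config.mutation_rate_non_truncating)
        k_s = rng.poisson(config.mutation_rate_silent)
        for _ in range(k_t):
            records.append(
                MutationRecord(sid, genes[rng.integers(len(genes))],
                               TRUNCATING_CLASSES[rng.integers(len(TRUNCATING_CLASSES))])
            )
        for _ in range(k_n):
            records.append(
                MutationRecord(sid, genes[rng.integers(len(genes))],
                               NON_TRUNCATING_CLASSES[rng.integers(len(NON_TRUNCATING_CLASSES))])
            )
        for _ in range(k_s):
            records.append(MutationRecord(sid, genes[rng.integers(len(genes))], "Silent"))
    return records


def simulate_single_cell_counts(
    config: SimulationConfig,
    n_cells: int = 200,
    n_genes: int = 100,
    mean_count: float = 2.0,
    mito_genes: int = 5,
) -> ExpressionMatrix:
    """A small sparse count matrix (genes x cells) for QC-filter exercises,
    with a handful of ``MT-`` genes carrying elevated counts in some cells."""
    rng = np.random.default_rng(config.seed)
    genes = [f"MT-G{i}" for i in range(1, mito_genes + 1)] + [
        f"SC{i:04d}" for i in range(1, n_genes - mito_genes + 1)
    ]
    cells = [f"CELL{i:04d}" for i in range(1, n_cells + 1)]
    counts = rng.poisson(mean_count, size=(len(genes), n_cells))
    # a fraction of cells are mito-heavy (dying-cell analogue)
    heavy = rng.random(n_cells) < 0.1
    counts[:mito_genes, heavy] += rng.poisson(mean_count * 20, size=(mito_genes, int(heavy.sum())))
    return ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=cells), scale="counts")


# ---------------------------------------------------------------------------
# Chromatin tracks
# ---------------------------------------------------------------------------


@dataclass
class ChromatinTruth:
    """Planted boundary/loop configuration of a simulated chromatin locus."""

    boundary_keys: list[tuple[str, int, int]]
    convergent_loops: list[tuple[tuple[str, int, int], tuple[str, int, int], int]]
    nonconvergent_loops: list[tuple[tuple[str, int, int], tuple[str, int, int], int]]
    decoy_keys: list[tuple[str, int, int]]
    tss_inside: list[str]
    tss_outside: list[str]


def simulate_chromatin_tracks(
    config: SimulationConfig,
) -> tuple[dict[str, list[GenomicInterval]], list[GenomicInterval], list[Linkage], pd.DataFrame, ChromatinTruth]:
    """Peak/motif/linkage tracks with planted convergent insulated-neighborhood
    boundaries plus decoys.

    Plants ``n_boundary_pairs`` convergent pairs (left motif "+", right "-")
    whose CTCF footprints are co-occupied by all three cohesin subunits and
    spanned by a linkage of ``linkage_count`` read pairs; adds
    ``n_nonconvergent_pairs`` cohesin-supported pairs with same-strand motifs
    and weak (count 2) linkages, and ``n_decoy_ctcf`` CTCF-only peaks with no
    cohesin.  One TSS is placed inside each convergent loop and one outside.
    """
    chrom = "chr1"
    peak_w = 400
    span = 200_000
    slot = 500_000

    ctcf: list[GenomicInterval] = []
    rad21: list[GenomicInterval] = []
    stag1: list[GenomicInterval] = []
    smc1a: list[GenomicInterval] = []
    motifs: list[GenomicInterval] = []
    linkages: list[Linkage] = []
    tss_rows = []
    truth = ChromatinTruth([], [], [], [], [], [])

    def plant_pair(idx: int, left_strand: str, right_strand: str, count: int):
        o = 1_000_000 + idx * slot
        left = GenomicInterval(chrom, o, o + peak_w)
        right = GenomicInterval(chrom, o + span, o + span + peak_w)
        for side, strand in ((left, left_strand), (right, right_strand)):
            ctcf.append(side)
            rad21.append(GenomicInterval(chrom, side.start + 50, side.end - 50))
            stag1.append(GenomicInterval(chrom, side.start + 60, side.end - 60))
            smc1a.append(GenomicInterval(chrom, side.start + 70, side.end - 70))
            motifs.append(GenomicInterval(chrom, side.start + 180, side.start + 200, strand=strand))
        linkages.append(
            Linkage(
                GenomicInterval(chrom, left.start - 100, left.end + 100),
                GenomicInterval(chrom, right.start - 100, right.end + 100),
                count=count,
            )
        )
        lk = (chrom, left.start, left.end)
        rk = (chrom, right.start, right.end)
        truth.boundary_keys.extend([lk, rk])
        return lk, rk

    for i in range(config.n_boundary_pairs):
        lk, rk = plant_pair(i, "+", "-", config.linkage_count)
        truth.convergent_loops.append((lk, rk, config.linkage_count))
        o = 1_000_000 + i * slot
        gene_in = f"INLOOP{i + 1}"
        tss_rows.append({"gene": gene_in, "chrom": chrom, "pos": o + span // 2, "strand": "+"})
        truth.tss_inside.append(gene_in)
        gene_out = f"OUTLOOP{i + 1}"
        tss_rows.append({"gene": gene_out, "chrom": chrom, "pos": o + slot - 50_000, "strand": "-"})
        truth.tss_outside.append(gene_out)

    for i in range(config.n_nonconvergent_pairs):
        lk, rk = plant_pair(config.n_boundary_pairs + i, "+", "+", 2)
        truth.nonconvergent_loops.append((lk, rk, 2))

    base_decoy = 1_000_000 + (config.n_boundary_pairs + config.n_nonconvergent_pairs) * slot
    for i in range(config.n_decoy_ctcf):
        o = base_decoy + i * 10_000
        peak = GenomicInterval(chrom, o, o + peak_w)
        ctcf.append(peak)
        motifs.append(GenomicInterval(chrom, o + 180, o + 200, strand="+"))
        truth.decoy_keys.append((chrom, peak.start, peak.end))

    tracks = {"CTCF": ctcf, "RAD21": rad21, "STAG1": stag1, "SMC1A": smc1a}
    tss = pd.DataFrame(tss_rows)
    return tracks, motifs, linkages, tss, truth
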