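"""End-to-end analysis drivers combining the module-level operations.

These wire the synthetic cohorts through the scoring and comparison steps
the way the corresponding tumor-cohort analyses are run: paired
delta-enrichment genotype comparisons, and the three-way quartile/pathway
intersection that asks whether an immune program tracks basal-program
elevation consistently across cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import delta_paired_scores, gsva_scores, stratify_quartiles
from .immune_tmb import intersect_pathways, pathway_differential_enrichment
from .io_formats import GeneSet
from .synthetic_data import PlantedTruth, SimulationConfig, simulate_paired_cohort

__all__ = [
    "delta_basal_genotype_test",
    "decoy_gene_sets",
    "quartile_pathway_comparison",
    "genotype_delta_pathway_comparison",
    "three_way_immune_intersection",
]


def delta_basal_genotype_test(config: SimulationConfig) -> tuple[float, pd.DataFrame]:
    """Mutant-vs-WT Mann-Whitney test on the paired delta GSVA score of the
    planted basal program.  Returns (two-sided p, delta table)."""
    matrix, ann, _, truth = simulate_paired_cohort(config)
    table = gsva_scores(matrix, [truth.basal_set()])
    delta = delta_paired_scores(table, ann)
    genotype = ann.drop_duplicates("patient_id").set_index("patient_id")["genotype"]
    mut = delta.loc[genotype == "mutant", "planted_basal"]
    wt = delta.loc[genotype == "WT", "planted_basal"]
    p = float(stats.mannwhitneyu(mut, wt, alternative="two-sided").pvalue)
    return p, delta


def decoy_gene_sets(
    gene_ids: list[str], n_sets: int = 8, size: int = 15, seed: int = 12345
) -> list[GeneSet]:
    """Fixed decoy pathways drawn from background (non-program) genes, so
    multiplicity correction across the set collection has something to do."""
    background = [g for g in gene_ids if g.startswith("GENE")]
    if len(background) < size:
        raise ValueError("not enough background genes for decoy sets")
    rng = np.random.default_rng(seed)
    return [
        GeneSet.from_iterable(f"decoy{i + 1}", rng.choice(background, size, replace=False))
        for i in range(n_sets)
    ]


def _score_collection(matrix, truth: PlantedTruth, extra: list[GeneSet]):
    sets = [truth.immune_set(), truth.basal_set()] + extra
    table = gsva_scores(matrix, sets + [truth.bck_set()])
    return table, [s.name for s in sets]


def quartile_pathway_comparison(config: SimulationConfig, name: str) -> pd.DataFrame:
    """BCK-high vs BCK-low quartile pathway comparison in one cohort.

    Samples are stratified by the GSVA score of the six-gene BCK set and
    the upper/lower quartiles compared per pathway.  Cohort heterogeneity
    of the basal program is required for the quartiles to differ, so this
    design switches the latent basal-activity SD on (1.0) unless the
    config already sets it.
    """
    cfg = config if config.basal_activity_sd > 0 else config.with_(basal_activity_sd=1.0)
    matrix, ann, _, truth = simulate_paired_cohort(cfg)
    table, set_names = _score_collection(matrix, truth, decoy_gene_sets(matrix.gene_ids))
    strat = stratify_quartiles(table.scores["BCK"])
    return pathway_differential_enrichment(
        table.scores[set_names], strat.high, strat.low, name=name
    )


def genotype_delta_pathway_comparison(config: SimulationConfig, name: str) -> pd.DataFrame:
    """Mutant vs WT pathway comparison on paired delta scores."""
    matrix, ann, _, truth = simulate_paired_cohort(config)
    table, set_names = _score_collection(matrix, truth, decoy_gene_sets(matrix.gene_ids))
    delta = delta_paired_scores(table.scores[set_names], ann)
    genotype = ann.drop_duplicates("patient_id").set_index("patient_id")["genotype"]
    return pathway_differential_enrichment(
        delta,
        list(genotype.index[genotype == "mutant"]),
        list(genotype.index[genotype == "WT"]),
        name=name,
    )


def three_way_immune_intersection(
    config: SimulationConfig, seed: int
) -> tuple[set[str], list[pd.DataFrame]]:
    """The three-comparison pathway intersection.

    Two independently simulated cohorts contribute BCK-high-vs-low quartile
    comparisons and a third paired cohort contributes the mutant-vs-WT
    delta comparison; the direction-aware intersection of their enriched
    pathways is returned together with the per-comparison tables.
    """
    results = [
        quartile_pathway_comparison(config.with_(seed=seed + 1), "cohort1"),
        quartile_pathway_comparison(config.with_(seed=seed + 2), "cohort2"),
        genotype_delta_pathway_comparison(config.with_(seed=seed + 3), "mut_vs_wt"),
    ]
    intersection, _ = intersect_pathways(results)
    return intersection, results
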