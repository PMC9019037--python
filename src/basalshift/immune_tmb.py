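"""Tumor mutation burden, pathway-intersection and immune scoring.

TMB uses the weighted definition 2 x (truncating mutations) +
(non-truncating mutations) per sample, with the truncating class covering
nonsense, frame-shift indels and splice-site variants and the
non-truncating class covering missense, in-frame indels and nonstop
variants.  Any other variant classification (e.g. Silent) is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet, MutationRecord
from .signatures import benjamini_hochberg

__all__ = [
    "TRUNCATING_CLASSES",
    "NON_TRUNCATING_CLASSES",
    "TmbRecord",
    "classify_variant",
    "compute_tmb",
    "pathway_differential_enrichment",
    "intersect_pathways",
    "immune_cell_scores",
    "percent_expressing",
]

TRUNCATING_CLASSES = (
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)

NON_TRUNCATING_CLASSES = (
    "Missense_Mutation",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Nonstop_Mutation",
)


@dataclass(frozen=True)
class TmbRecord:
    sample_id: str
    n_truncating: int
    n_non_truncating: int

    @property
    def tmb(self) -> float:
        return 2.0 * self.n_truncating + self.n_non_truncating


def classify_variant(variant_classification: str) -> str:
    """Map a MAF Variant_Classification token to ``truncating`` /
    ``non_truncating`` / ``excluded``."""
    if variant_classification in TRUNCATING_CLASSES:
        return "truncating"
    if variant_classification in NON_TRUNCATING_CLASSES:
        return "non_truncating"
    return "excluded"


def compute_tmb(mutation_table: Iterable[MutationRecord]) -> list[TmbRecord]:
    """Weighted tumor mutation burden per sample: 2*truncating + non-truncating.

    Excluded-class rows are ignored.  Samples absent from the table get no
    record (zero-filling is the caller's decision).  Output order follows
    first appearance of each sample.
    """
    trunc: dict[str, int] = {}
    nontrunc: dict[str, int] = {}
    order: list[str] = []
    for rec in mutation_table:
        cls = classify_variant(rec.variant_classification)
        if cls == "excluded":
            continue
        if rec.sample_id not in trunc:
            trunc[rec.sample_id] = 0
            nontrunc[rec.sample_id] = 0
            order.append(rec.sample_id)
        if cls == "truncating":
            trunc[rec.sample_id] += 1
        else:
            nontrunc[rec.sample_id] += 1
    return [TmbRecord(s, trunc[s], nontrunc[s]) for s in order]


# ---------------------------------------------------------------------------
# Pathway enrichment comparisons
# ---------------------------------------------------------------------------


def pathway_differential_enrichment(
    score_table: pd.DataFrame,
    group_interest: Sequence[str],
    group_other: Sequence[str],
    fdr: float = 0.05,
    name: str = "comparison",
) -> pd.DataFrame:
    """Per-gene-set two-sided Mann-Whitney comparison of per-sample scores.

    ``score_table`` is samples x gene-sets (e.g. GSVA scores, or paired
    delta scores with patients as rows).  BH correction is applied across
    sets; a set is called *enriched* when ``q < fdr`` and its median score
    in the group of interest exceeds the median in the other group.

    Returns a DataFrame indexed by set name with columns
    ``statistic, p, q, direction, enriched`` plus a ``comparison`` label.
    """
    gi = list(group_interest)
    go = list(group_other)
    missing = [s for s in gi + go if s not in score_table.index]
    if missing:
        raise KeyError(f"samples not in score table: {missing[:5]}")
    if set(gi) & set(go):
        raise ValueError("groups must be disjoint")
    a = score_table.loc[gi]
    b = score_table.loc[go]
    rows = []
    for set_name in score_table.columns:
        x = a[set_name].to_numpy(float)
        y = b[set_name].to_numpy(float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = 0.5 * len(x) * len(y), 1.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        up = float(np.median(x)) > float(np.median(y))
        rows.append({"set": set_name, "statistic": stat, "p": p, "direction": "up" if up else "down"})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["enriched"] = (out["q"] < fdr) & (out["direction"] == "up")
    out["comparison"] = name
    return out


def intersect_pathways(
    results: Sequence[pd.DataFrame],
) -> tuple[set[str], dict[frozenset, int]]:
    """Direction-aware intersection of enriched sets across comparisons,
    plus Venn region counts.

    Each element of ``results`` comes from
    :func:`pathway_differential_enrichment`.  Returns the set names enriched
    in *every* comparison and a mapping from each nonempty comparison-index
    subset to the number of sets enriched in exactly those comparisons.
    """
    if len(results) < 2:
        raise ValueError("need at least two comparisons to intersect")
    enriched_sets = [set(r.index[r["enriched"]]) for r in results]
    intersection = set.intersection(*enriched_sets)
    union = set.union(*enriched_sets)
    venn: dict[frozenset, int] = {}
    k = len(enriched_sets)
    for r in range(1, k + 1):
        for combo in combinations(range(k), r):
            venn[frozenset(combo)] = 0
    for s in union:
        membership = frozenset(i for i, es in enumerate(enriched_sets) if s in es)
        venn[membership] += 1
    return intersection, venn


# ---------------------------------------------------------------------------
# Immune-cell-type scores and percent expressing
# ---------------------------------------------------------------------------


def immune_cell_scores(
    matrix: ExpressionMatrix,
    celltype_signatures: Iterable[GeneSet],
) -> pd.DataFrame:
    """Mean-z cell-type scores: per-gene z across samples, averaged over the
    signature's genes present in the matrix.  Zero-variance genes are
    skipped with a warning.  Returns samples x cell-types."""
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    usable = sd > 0
    if (~usable).any():
        warnings.warn(f"{int((~usable).sum())} zero-variance genes skipped in z-scoring")
    z = vals.loc[usable].sub(vals.loc[usable].mean(axis=1), axis=0).div(sd[usable], axis=0)
    out = {}
    for sig in celltype_signatures:
        genes = [g for g in sig.genes if g in z.index]
        if not genes:
            raise KeyError(f"signature {sig.name!r} shares no usable genes with the matrix")
        out[sig.name] = z.loc[genes].mean(axis=0)
    return pd.DataFrame(out)


def percent_expressing(
    counts: ExpressionMatrix,
    gene: str,
    groups: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Fraction of each group's cells with count > 0 for ``gene``."""
    if gene not in counts.values.index:
        raise KeyError(f"gene {gene!r} not present in the count matrix")
    row = counts.values.loc[gene]
    out = {}
    for name, cells in groups.items():
        missing = [c for c in cells if c not in row.index]
        if missing:
            raise KeyError(f"group {name!r}: cells not in matrix: {missing[:5]}")
        sub = row.loc[list(cells)]
        out[name] = float((sub > 0).mean())
    return pd.Series(out, name=gene)
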