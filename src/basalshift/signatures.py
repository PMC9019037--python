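"""Derivation of luminal/basal (and knockdown) gene signatures.

Three derivation routes are provided, mirroring how reference signatures
are built from labeled expression panels:

* a two-group FDR filter over a candidate (intrinsic) gene list —
  significantly higher genes in each class become that class's markers;
* the intersection of the top-N most increased genes across two
  independent comparisons;
* the top-N most downregulated genes after a factor knockdown.

The differential-expression statistic is the two-sided Mann-Whitney U
test: the downstream consumer of this module is a gene list, not an
effect estimate, so a distribution-free rank test suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet

__all__ = [
    "SignaturePair",
    "differential_expression",
    "benjamini_hochberg",
    "derive_two_group_signature",
    "derive_topN_intersection_signature",
    "derive_knockdown_signature",
]


@dataclass(frozen=True)
class SignaturePair:
    """A luminal gene set paired with a basal gene set."""

    basal: GeneSet
    luminal: GeneSet
    provenance: str = "two_group_filter"

    def __post_init__(self) -> None:
        overlap = set(self.basal.genes) & set(self.luminal.genes)
        if overlap:
            raise ValueError(f"basal/luminal sets overlap: {sorted(overlap)[:5]}")


def benjamini_hochberg(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j, capped at 1;
    ties keep input order stable.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(
    matrix: ExpressionMatrix,
    group_a_ids: list[str],
    group_b_ids: list[str],
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U comparison of group B vs group A.

    ``log2_fc`` is mean(B) - mean(A) on the log2 scale.  The test uses the
    exact null distribution when the combined group size is at most 20 (and
    the gene has no cross-group ties), otherwise the normal approximation
    with tie correction.  Genes with zero variance across both groups get
    ``p = 1``, ``log2_fc = 0`` and are flagged.  q-values are BH-adjusted
    across all genes.

    Returns a DataFrame indexed by gene with columns
    ``log2_fc, p_value, q_value, zero_variance``.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in a_ids + b_ids if s not in matrix.values.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing[:5]}")

    a = matrix.values[a_ids].to_numpy(float)
    b = matrix.values[b_ids].to_numpy(float)
    log2_fc = b.mean(axis=1) - a.mean(axis=1)

    combined = np.concatenate([a, b], axis=1)
    zero_var = np.ptp(combined, axis=1) == 0

    n_total = len(a_ids) + len(b_ids)
    p = np.ones(matrix.n_genes)
    if n_total <= 20:
        for i in range(matrix.n_genes):
            if zero_var[i]:
                continue
            has_ties = len(np.unique(combined[i])) < n_total
            method = "asymptotic" if has_ties else "exact"
            p[i] = stats.mannwhitneyu(
                b[i], a[i], alternative="two-sided", method=method
            ).pvalue
    else:
        keep = ~zero_var
        if keep.any():
            res = stats.mannwhitneyu(
                b[keep], a[keep], alternative="two-sided", method="asymptotic", axis=1
            )
            p[keep] = res.pvalue
    log2_fc = np.where(zero_var, 0.0, log2_fc)

    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": benjamini_hochberg(p),
            "zero_variance": zero_var,
        },
        index=matrix.values.index,
    )
    return out


def derive_two_group_signature(
    de_records: pd.DataFrame,
    candidate_genes: list[str] | None = None,
    fdr_cutoff: float = 0.01,
    basal_name: str = "basal_markers",
    luminal_name: str = "luminal_markers",
) -> SignaturePair:
    """FDR-filter signature derivation over a candidate gene list.

    With basal as group B in the DE comparison: candidates with
    ``q < fdr_cutoff`` and positive fold change become basal markers,
    those with negative fold change luminal markers.
    """
    if candidate_genes is None:
        candidates = de_records.index
    else:
        missing = [g for g in candidate_genes if g not in de_records.index]
        if missing:
            raise KeyError(f"candidate genes absent from DE table: {missing[:5]}")
        candidates = pd.Index(candidate_genes)
    sub = de_records.loc[candidates]
    sig = sub["q_value"] < fdr_cutoff
    basal = list(sub.index[sig & (sub["log2_fc"] > 0)])
    luminal = list(sub.index[sig & (sub["log2_fc"] < 0)])
    return SignaturePair(
        basal=GeneSet(basal_name, tuple(basal)),
        luminal=GeneSet(luminal_name, tuple(luminal)),
        provenance="two_group_filter",
    )


def _rank_by_fc(de: pd.DataFrame, ascending: bool) -> pd.DataFrame:
    # primary key fold change, ties by smaller p, then lexicographic gene id
    d = de.copy()
    d["_gene"] = d.index
    return d.sort_values(
        ["log2_fc", "p_value", "_gene"],
        ascending=[ascending, True, True],
        kind="stable",
    )


def derive_topN_intersection_signature(
    de_1: pd.DataFrame,
    de_2: pd.DataFrame,
    n: int = 200,
    significance_q: float | None = 0.05,
    name: str = "topN_intersection",
) -> GeneSet:
    """Intersect the top-``n`` most increased genes of two comparisons.

    Genes are ranked by descending log2 fold change among positive-fc genes
    (optionally gated at ``q < significance_q``); ties break by smaller p,
    then lexicographic gene id.  If fewer than ``n`` genes qualify in a
    comparison, all qualifying genes are used with a warning.
    """
    if not de_1.index.equals(de_2.index) and set(de_1.index) != set(de_2.index):
        raise ValueError("the two DE tables must cover the same gene universe")
    tops = []
    for de in (de_1, de_2):
        pos = de[de["log2_fc"] > 0]
        if significance_q is not None:
            pos = pos[pos["q_value"] < significance_q]
        if len(pos) < n:
            warnings.warn(
                f"only {len(pos)} genes qualify for a top-{n} list; using all"
            )
        ranked = _rank_by_fc(pos, ascending=False)
        tops.append(set(ranked.index[:n]))
    inter = tops[0] & tops[1]
    if not inter:
        warnings.warn("top-N lists do not intersect; returning an empty set")
    return GeneSet.from_iterable(name, sorted(inter))


def derive_knockdown_signature(
    de_records: pd.DataFrame,
    n: int = 100,
    direction: str = "down",
    name: str = "knockdown_signature",
) -> GeneSet:
    """Top-``n`` most down- (or up-) regulated genes of a knockdown comparison."""
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if direction == "down":
        pool = de_records[de_records["log2_fc"] < 0]
        ranked = _rank_by_fc(pool, ascending=True)
    else:
        pool = de_records[de_records["log2_fc"] > 0]
        ranked = _rank_by_fc(pool, ascending=False)
    if len(pool) < n:
        warnings.warn(f"only {len(pool)} {direction}-regulated genes; using all")
    return GeneSet.from_iterable(name, ranked.index[:n])
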