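"""Nearest-centroid subtype calling and cross-comparison concordance.

Subtype calling follows the intrinsic-subtype nearest-centroid idea:
reference centroids are per-gene medians within each labeled reference
class, a new profile is assigned to the subtype whose centroid it
correlates with best (Spearman), and a confidence readout is derived by
normalizing the positive correlations.  Correlation-based calling is
invariant to any strictly monotone transform of the profile, so
log/linear scale mismatches do not change the call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "CentroidModel",
    "SubtypeCall",
    "build_centroids",
    "call_subtype",
    "call_subtypes",
    "log_fold_changes",
    "classify_concordance",
]


@dataclass
class CentroidModel:
    """Genes x subtypes centroid matrix (median log2 expression per class)."""

    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        if self.centroids.shape[1] < 2:
            raise ValueError("a centroid model needs at least 2 subtypes")
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate genes in centroid model")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class SubtypeCall:
    sample_id: str
    label: str
    probabilities: pd.Series  # NaN-valued when no centroid correlates positively
    correlations: pd.Series
    defined: bool = True  # False when all correlations <= 0


def build_centroids(
    reference: ExpressionMatrix,
    labels: pd.Series,
    statistic: str = "median",
) -> CentroidModel:
    """Per-gene median (or mean) within each labeled reference class."""
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    labels = labels.reindex(reference.values.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:5])
        raise KeyError(f"reference samples without a label: {missing}")
    cols = {}
    for cls, samples in labels.groupby(labels).groups.items():
        block = reference.values[list(samples)]
        cols[str(cls)] = block.median(axis=1) if statistic == "median" else block.mean(axis=1)
    return CentroidModel(pd.DataFrame(cols))


def call_subtype(profile: pd.Series, model: CentroidModel) -> SubtypeCall:
    """Assign a single profile to the best-correlated centroid.

    Spearman correlation is computed over the model gene list (genes shared
    with the profile).  Confidence for subtype s is
    max(rho_s, 0) / sum_t max(rho_t, 0); if every correlation is <= 0 the
    label is still the argmax but probabilities are flagged undefined.
    Exact correlation ties break deterministically by subtype label order,
    with a warning.
    """
    shared = [g for g in model.genes if g in profile.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared with the centroid model (<3)")
    x = profile.loc[shared].to_numpy(float)
    rho = {}
    for s in model.subtypes:
        c = model.centroids.loc[shared, s].to_numpy(float)
        r = stats.spearmanr(x, c).statistic
        rho[s] = float(r) if np.isfinite(r) else 0.0
    corr = pd.Series(rho)
    best = corr.max()
    winners = list(corr.index[corr == best])
    if len(winners) > 1:
        warnings.warn(
            f"correlation tie between {winners}; choosing {sorted(winners)[0]!r}"
        )
    label = sorted(winners)[0]
    pos = corr.clip(lower=0.0)
    total = pos.sum()
    if total > 0:
        probs = pos / total
        defined = True
    else:
        probs = pd.Series(np.nan, index=corr.index)
        defined = False
    return SubtypeCall(
        sample_id=str(profile.name) if profile.name is not None else "",
        label=label,
        probabilities=probs,
        correlations=corr,
        defined=defined,
    )


def call_subtypes(matrix: ExpressionMatrix, model: CentroidModel) -> pd.DataFrame:
    """Call every sample of a matrix; returns a table with label and the
    winning subtype's confidence."""
    rows = []
    for sid in matrix.sample_ids:
        call = call_subtype(matrix.values[sid], model)
        rows.append(
            {
                "sample_id": sid,
                "label": call.label,
                "probability": float(call.probabilities.get(call.label, np.nan)),
                "defined": call.defined,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def log_fold_changes(
    matrix: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.Series:
    """Per-gene mean(B) - mean(A) on the log2 scale."""
    missing = [s for s in list(group_a) + list(group_b) if s not in matrix.values.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing[:5]}")
    return (
        matrix.values[list(group_b)].mean(axis=1)
        - matrix.values[list(group_a)].mean(axis=1)
    ).rename("log2_fc")


def classify_concordance(
    fc_tables: list[pd.Series], min_abs_fc: float = 0.0
) -> pd.DataFrame:
    """Classify genes as consistently up/down across >= 2 comparisons.

    ``consistent_up`` requires log2_fc > min_abs_fc in every comparison,
    ``consistent_down`` log2_fc < -min_abs_fc in every comparison
    (strict inequalities); everything else is ``inconsistent``.
    """
    if len(fc_tables) < 2:
        raise ValueError("need at least two comparisons")
    if min_abs_fc < 0:
        raise ValueError("min_abs_fc must be >= 0")
    genes = fc_tables[0].index
    for t in fc_tables[1:]:
        if not genes.equals(t.index) and set(genes) != set(t.index):
            raise ValueError("comparisons must cover the same gene universe")
    fc = pd.DataFrame({i: t.reindex(genes) for i, t in enumerate(fc_tables)})
    up = (fc > min_abs_fc).all(axis=1)
    down = (fc < -min_abs_fc).all(axis=1)
    cls = pd.Series(
        np.where(up, "consistent_up", np.where(down, "consistent_down", "inconsistent")),
        index=genes,
        name="class",
    )
    out = fc.copy()
    out.columns = [f"log2_fc_{i + 1}" for i in range(fc.shape[1])]
    out["class"] = cls
    return out
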