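"""Single-sample gene-set enrichment scoring.

Two statistics are implemented:

* **GSVA-style score** — a Gaussian-kernel ECDF estimate per gene across
  samples, followed, per sample, by a weighted Kolmogorov-Smirnov-like
  random walk down the gene ranking.  With gene ranks r in {1..p} and
  rank weights w = |p/2 - r| raised to the exponent tau, the walk is

      nu(l) = sum_{i<=l, i in set} w_i^tau / sum_{i in set} w_i^tau
            - sum_{i<=l, i not in set} 1 / (p - m)

  and the score is either ES+ + ES- (``magnitude_difference``, the
  default) or the walk value of largest magnitude (``max_deviation``).

* **ssGSEA-style score** — per-sample ranking by expression with rank
  weights r^alpha (alpha = 0.25 as in immune-score applications) and the
  unnormalized running-sum difference summed over all positions.

Ranking ties break by gene identifier, so scores are invariant to the
row order of the input matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_formats import ExpressionMatrix, GeneSet

__all__ = [
    "EnrichmentParams",
    "EnrichmentScoreTable",
    "StratificationResult",
    "kernel_cdf_stat",
    "gsva_scores",
    "ssgsea_scores",
    "delta_paired_scores",
    "stratify_quartiles",
]


@dataclass(frozen=True)
class EnrichmentParams:
    """Tunables of the enrichment statistics.

    tau: rank-weight exponent of the GSVA walk (>= 0).
    mode: "magnitude_difference" (ES+ + ES-) or "max_deviation".
    kernel_bandwidth_factor: h_i = s_i * factor with s_i the gene's sample SD.
    alpha: ssGSEA rank-weight exponent.
    """

    tau: float = 1.0
    mode: str = "magnitude_difference"
    kernel_bandwidth_factor: float = 0.25
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.kernel_bandwidth_factor <= 0:
            raise ValueError("kernel_bandwidth_factor must be > 0")
        if self.mode not in ("magnitude_difference", "max_deviation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class EnrichmentScoreTable:
    """Samples x gene-sets enrichment scores (NaN for error sets)."""

    scores: pd.DataFrame
    params: EnrichmentParams
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class StratificationResult:
    """Quartile stratification of a per-sample score."""

    labels: pd.Series  # values in {"high", "low", "mid"}
    q1: float
    q3: float

    @property
    def high(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])


def kernel_cdf_stat(
    matrix: ExpressionMatrix, kernel_bandwidth_factor: float = 0.25
) -> pd.DataFrame:
    """Gaussian-kernel ECDF statistic, genes x samples.

    z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i) with h_i = s_i * factor
    (s_i the gene's across-sample SD); a zero-variance gene gets 0.5 for
    every sample.
    """
    vals = matrix.values.to_numpy(float)
    p, n = vals.shape
    if n < 2:
        raise ValueError("kernel ECDF needs at least 2 samples")
    sd = vals.std(axis=1, ddof=1)
    out = np.full((p, n), 0.5)
    # chunk over genes to bound the (g, n, n) intermediate
    idx = np.where(sd > 0)[0]
    chunk = max(1, int(4_000_000 // max(n * n, 1)))
    for s in range(0, idx.size, chunk):
        rows = idx[s : s + chunk]
        x = vals[rows]
        h = sd[rows] * kernel_bandwidth_factor
        diff = (x[:, :, None] - x[:, None, :]) / h[:, None, None]
        out[rows] = ndtr(diff).mean(axis=2)
    return pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering genes by value descending, ties by gene id ascending."""
    return np.lexsort((gene_ids, -values))


def gsva_scores(
    matrix: ExpressionMatrix,
    gene_sets: list[GeneSet],
    params: EnrichmentParams | None = None,
) -> EnrichmentScoreTable:
    """GSVA-style per-sample enrichment scores for a gene-set collection.

    A set whose intersection with the matrix genes is empty, or covers the
    whole matrix, gets a per-set error entry (NaN column); the remaining
    sets are still scored.
    """
    params = params or EnrichmentParams()
    z = kernel_cdf_stat(matrix, params.kernel_bandwidth_factor).to_numpy()
    gene_ids = matrix.values.index.to_numpy(dtype=object).astype(str)
    p, n = z.shape
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    memberships: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}
    for gs in gene_sets:
        rows = [gene_pos[g] for g in gs.genes if g in gene_pos]
        m = len(rows)
        if m == 0:
            errors[gs.name] = "no genes of the set are present in the matrix"
        elif m >= p:
            errors[gs.name] = "gene set covers the whole matrix (m = p)"
        else:
            mask = np.zeros(p, dtype=bool)
            mask[rows] = True
            memberships[gs.name] = mask

    scores = np.full((n, len(gene_sets)), np.nan)
    names = [gs.name for gs in gene_sets]
    ranks = np.empty(p, dtype=float)
    for j in range(n):
        order = _rank_order(z[:, j], gene_ids)
        ranks[order] = np.arange(1, p + 1)
        w = np.abs(p / 2.0 - ranks) ** params.tau
        for c, name in enumerate(names):
            if name not in memberships:
                continue
            mask = memberships[name]
            m = int(mask.sum())
            in_ordered = mask[order]
            w_ordered = w[order]
            w_in = np.where(in_ordered, w_ordered, 0.0)
            denom = w_in.sum()
            if denom == 0.0:
                # every set gene sits exactly at the central rank weight 0;
                # fall back to uniform set weights for this sample
                w_in = in_ordered.astype(float)
                denom = float(m)
            nu = np.cumsum(w_in) / denom - np.cumsum(~in_ordered) / (p - m)
            if params.mode == "magnitude_difference":
                scores[j, c] = max(0.0, nu.max()) + min(0.0, nu.min())
            else:
                scores[j, c] = nu[np.argmax(np.abs(nu))]
    table = pd.DataFrame(scores, index=matrix.values.columns, columns=names)
    return EnrichmentScoreTable(table, params, errors)


def ssgsea_scores(
    matrix: ExpressionMatrix, gene_set: GeneSet, alpha: float = 0.25
) -> pd.Series:
    """ssGSEA-style unnormalized running-sum score per sample.

    Genes are ranked by expression descending per sample; the gene at the
    top receives rank weight p, the bottom 1, and set positions are
    weighted by rank^alpha.  The score is the sum over all list positions
    of (weighted in-set running fraction - out-of-set running fraction).
    """
    vals = matrix.values.to_numpy(float)
    gene_ids = matrix.values.index.to_numpy(dtype=object).astype(str)
    p, n = vals.shape
    mask = np.isin(gene_ids, list(gene_set.genes))
    m = int(mask.sum())
    if m == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the matrix")
    if m >= p:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole matrix")
    out = np.empty(n)
    for j in range(n):
        order = _rank_order(vals[:, j], gene_ids)
        in_ordered = mask[order]
        r = p - np.arange(p, dtype=float)  # position l has rank weight p - l + 1
        w_in = np.where(in_ordered, r**alpha, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~in_ordered) / (p - m)
        out[j] = float(np.sum(p_in - p_out))
    return pd.Series(out, index=matrix.values.columns, name=gene_set.name)


def delta_paired_scores(
    score_table: EnrichmentScoreTable | pd.DataFrame,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Metastasis-minus-primary score per patient per gene set.

    ``annotations`` is indexed by sample id with columns ``patient_id`` and
    ``lesion`` ("primary"/"metastasis").  Patients lacking either lesion in
    the score table are excluded with a warning; a duplicated lesion for a
    patient is an error.
    """
    scores = score_table.scores if isinstance(score_table, EnrichmentScoreTable) else score_table
    for col in ("patient_id", "lesion"):
        if col not in annotations.columns:
            raise KeyError(f"annotations lack required column {col!r}")
    ann = annotations[annotations.index.isin(scores.index)]
    rows = {}
    for patient, grp in ann.groupby("patient_id", sort=False):
        lesions = grp["lesion"].tolist()
        if lesions.count("primary") > 1 or lesions.count("metastasis") > 1:
            raise ValueError(f"patient {patient!r} has a duplicated lesion")
        if "primary" not in lesions or "metastasis" not in lesions:
            warnings.warn(f"patient {patient!r} is unpaired; excluded")
            continue
        pri = grp.index[grp["lesion"] == "primary"][0]
        met = grp.index[grp["lesion"] == "metastasis"][0]
        rows[patient] = scores.loc[met] - scores.loc[pri]
    if not rows:
        raise ValueError("no fully paired patients found")
    return pd.DataFrame(rows).T.rename_axis("patient_id")


def stratify_quartiles(scores: pd.Series) -> StratificationResult:
    """Label samples high (score >= Q3), low (score <= Q1) or mid.

    Quartiles are empirical 25th/75th percentiles with linear
    interpolation; ties at a threshold go to the extreme label.  If all
    scores are equal the split is undefined: every sample is labeled mid
    with a warning.
    """
    if len(scores) < 4:
        raise ValueError("quartile stratification needs at least 4 samples")
    vals = scores.to_numpy(float)
    q1 = float(np.percentile(vals, 25))
    q3 = float(np.percentile(vals, 75))
    if q1 == q3:
        warnings.warn("degenerate score distribution (Q1 == Q3); all samples labeled mid")
        labels = pd.Series("mid", index=scores.index)
        return StratificationResult(labels, q1, q3)
    labels = pd.Series(
        np.where(vals >= q3, "high", np.where(vals <= q1, "low", "mid")),
        index=scores.index,
    )
    return StratificationResult(labels, q1, q3)
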