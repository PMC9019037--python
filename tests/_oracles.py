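"""Independent brute-force oracles used across the test suite.

These are deliberately literal transcriptions of the defining formulas
(double loops, per-position walks, risk-set recomputation, all-pairs
overlap) and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def brute_kernel(vals: np.ndarray, factor: float = 0.25) -> np.ndarray:
    p, n = vals.shape
    out = np.full((p, n), 0.5)
    for i in range(p):
        s = vals[i].std(ddof=1)
        if s == 0:
            continue
        h = s * factor
        for j in range(n):
            out[i, j] = np.mean([norm.cdf((vals[i, j] - vals[i, k]) / h) for k in range(n)])
    return out


def brute_gsva(
    vals: np.ndarray,
    genes: list[str],
    set_genes: set[str],
    tau: float = 1.0,
    mode: str = "magnitude_difference",
    factor: float = 0.25,
) -> np.ndarray:
    """Step-by-step kernel-ECDF + weighted random-walk evaluation."""
    z = brute_kernel(vals, factor)
    p, n = vals.shape
    out = np.empty(n)
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-z[i, j], genes[i]))
        ranks = {i: pos + 1 for pos, i in enumerate(order)}
        w = {i: abs(p / 2 - ranks[i]) ** tau for i in range(p)}
        m = sum(1 for g in genes if g in set_genes)
        W = sum(w[i] for i in range(p) if genes[i] in set_genes)
        if W == 0:
            w = {i: 1.0 for i in range(p)}
            W = float(m)
        nu = []
        ci = co = 0.0
        for i in order:
            if genes[i] in set_genes:
                ci += w[i]
            else:
                co += 1
            nu.append(ci / W - co / (p - m))
        nu = np.array(nu)
        if mode == "magnitude_difference":
            out[j] = max(0.0, nu.max()) + min(0.0, nu.min())
        else:
            out[j] = nu[np.argmax(np.abs(nu))]
    return out


def brute_ssgsea(
    vals: np.ndarray, genes: list[str], set_genes: set[str], alpha: float = 0.25
) -> np.ndarray:
    p, n = vals.shape
    out = np.empty(n)
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-vals[i, j], genes[i]))
        m = sum(1 for g in genes if g in set_genes)
        rw = {i: (p - pos) ** alpha for pos, i in enumerate(order)}
        W = sum(rw[i] for i in range(p) if genes[i] in set_genes)
        tot = 0.0
        ci = co = 0.0
        for i in order:
            if genes[i] in set_genes:
                ci += rw[i]
            else:
                co += 1
            tot += ci / W - co / (p - m)
        out[j] = tot
    return out


def brute_bh(p_values: np.ndarray) -> np.ndarray:
    """Direct evaluation of q_i = min over {j : p_(j) >= p_i} of p_(j)*m/j."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(m) if p[order[j]] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


def brute_km(time: np.ndarray, event: np.ndarray):
    """Risk-set recomputation of the product-limit estimator."""
    ts = sorted(set(t for t, e in zip(time, event) if e == 1))
    surv = []
    s = 1.0
    for t in ts:
        n = sum(1 for tt in time if tt >= t)
        d = sum(1 for tt, e in zip(time, event) if tt == t and e == 1)
        s *= 1.0 - d / n
        surv.append(s)
    return np.array(ts), np.array(surv)


def brute_logrank(time, event, g1_mask):
    """Hand enumeration of risk sets for the two-group log-rank test."""
    ts = sorted(set(t for t, e in zip(time, event) if e == 1))
    o1 = e1 = v = 0.0
    for t in ts:
        at = [i for i, tt in enumerate(time) if tt >= t]
        n = len(at)
        n1 = sum(1 for i in at if g1_mask[i])
        d = sum(1 for i, (tt, e) in enumerate(zip(time, event)) if tt == t and e == 1)
        d1 = sum(
            1
            for i, (tt, e) in enumerate(zip(time, event))
            if tt == t and e == 1 and g1_mask[i]
        )
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = 0.0 if v == 0 else (o1 - e1) ** 2 / v
    return o1, e1, v, chi2


def brute_tmb(records, truncating: set[str], non_truncating: set[str]):
    """Row-by-row count oracle for the weighted mutation burden."""
    out: dict[str, list[int]] = {}
    for r in records:
        if r.variant_classification in truncating:
            out.setdefault(r.sample_id, [0, 0])[0] += 1
        elif r.variant_classification in non_truncating:
            out.setdefault(r.sample_id, [0, 0])[1] += 1
    return {s: 2 * t + n for s, (t, n) in out.items()}


def intervals_overlap(a, b) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_boundaries(ctcf, cohesin_tracks, motifs, window=0, min_cohesin=2):
    """Quadratic all-pairs overlap oracle for boundary calling."""
    out = []
    for peak in ctcf:
        support = []
        for name, track in cohesin_tracks.items():
            hit = any(
                peak.chrom == c.chrom
                and (peak.start - window) < (c.end + window)
                and (c.start - window) < (peak.end + window)
                for c in track
            )
            if hit:
                support.append(name)
        if len(support) < min_cohesin:
            continue
        hits = [m for m in motifs if intervals_overlap(peak, m)]
        strand = hits[0].strand if len(hits) == 1 and hits[0].strand in "+-" else "unknown"
        out.append(((peak.chrom, peak.start, peak.end), strand, tuple(support)))
    return out
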