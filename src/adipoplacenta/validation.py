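"""Cell-type reference profiling and qPCR validation statistics.

Gene sets are profiled against a cell-type x gene reference expression matrix
(arg-max cell type and per-gene z-scores across cell types).  qPCR validation
expresses each target as a ratio to a reference (housekeeping) gene,
2^(Ct_ref - Ct_target) under amplification efficiency 2, compares adiposity
groups with an exact Wilcoxon rank-sum test, and relates qPCR to
log2-transformed sequencing counts by Spearman correlation.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

EXACT_RANKSUM_MAX_N = 20
EXACT_SPEARMAN_MAX_N = 8


# ---------------------------------------------------------------------------
# Reference profiling
# ---------------------------------------------------------------------------

def reference_profile(genes, reference: pd.DataFrame) -> dict:
    """Profile genes against a cell-type x gene reference matrix.

    Returns a dict with:

    * ``profile`` — cell-type x gene slice for the genes present
    * ``argmax_type`` — Series mapping each present gene to its top cell type
    * ``zscores`` — per-gene z-score of expression across cell types (0
      everywhere for a uniform row)
    * ``not_expressed`` — requested genes absent from the reference
    """
    genes = list(genes)
    present = [g for g in genes if g in reference.columns]
    missing = [g for g in genes if g not in reference.columns]
    if not present:
        raise ValueError("none of the requested genes are in the reference")
    prof = reference[present]
    argmax = prof.idxmax(axis=0)
    mean = prof.mean(axis=0)
    sd = prof.std(axis=0, ddof=0)
    z = (prof - mean) / sd.replace(0.0, np.nan)
    z = z.fillna(0.0)
    return {"profile": prof, "argmax_type": argmax, "zscores": z,
            "not_expressed": missing}


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def qpcr_ratio(ct_target: float, ct_reference: float,
               efficiency: float = 2.0) -> float:
    """Relative expression of target vs reference: efficiency^(Ct_ref - Ct_target).

    Lower target Ct means higher expression; equal Cts give 1.  The default
    assumes perfect doubling per cycle.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency ** (ct_reference - ct_target))


def relative_expression_table(ct: pd.DataFrame, target_gene: str,
                              reference_gene: str,
                              efficiency: float = 2.0) -> pd.DataFrame:
    """Per-sample target:reference expression ratios from a long Ct table."""
    tgt = ct[ct["gene"] == target_gene].set_index("sample_id")["ct"]
    ref = ct[ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    samples = tgt.index.intersection(ref.index)
    if len(samples) == 0:
        raise ValueError("no samples have both target and reference Ct values")
    rows = [{"sample_id": s, "ct_target": float(tgt[s]),
             "ct_reference": float(ref[s]),
             "relative_expression": qpcr_ratio(tgt[s], ref[s], efficiency)}
            for s in samples]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of all C(n1+n2, n1) rank assignments (with mid-rank
    ties) for combined n <= 20; otherwise the normal approximation with
    continuity and tie corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    N = n1 + n2
    if N <= EXACT_RANKSUM_MAX_N:
        total = comb(N, n1)
        le = ge = 0
        eps = 1e-9
        for idx in itertools.combinations(range(N), n1):
            w = ranks[list(idx)].sum()
            if w <= w_obs + eps:
                le += 1
            if w >= w_obs - eps:
                ge += 1
        p = 2.0 * min(le, ge) / total
        return float(min(1.0, p))
    # normal approximation with tie correction
    u = w_obs - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = ((t_counts ** 3 - t_counts).sum()) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (abs(u - mean) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def signed_rank_test(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples (delegates to the
    standard implementation; exact mode for small n without ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return float(stats.wilcoxon(x, y).pvalue)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  The p-value is exact by
    enumeration of all n! rank permutations for n <= 8 and the
    t-approximation (df = n - 2) otherwise.  A constant input leaves rho
    undefined: returns (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        count = 0
        total = math.factorial(n)
        eps = 1e-12
        rx_c = rx - rx.mean()
        denom_x = math.sqrt((rx_c ** 2).sum())
        for perm in itertools.permutations(ry):
            py = np.asarray(perm)
            py_c = py - py.mean()
            denom = denom_x * math.sqrt((py_c ** 2).sum())
            r = float((rx_c * py_c).sum() / denom)
            if abs(r) >= abs(rho) - eps:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def qpcr_validation(ct: pd.DataFrame, counts: pd.DataFrame,
                    metadata: pd.DataFrame, target_gene: str,
                    reference_gene: str, efficiency: float = 2.0) -> dict:
    """Full qPCR validation for one target gene.

    Computes per-sample relative expression, a rank-sum comparison of LA vs HA
    samples within each maternal group, and the Spearman correlation between
    relative expression and log2-transformed normalized sequencing counts over
    all shared samples.
    """
    from .de import log_normalized

    rel = relative_expression_table(ct, target_gene, reference_gene,
                                    efficiency)
    md = metadata.set_index("sample_id")
    rel = rel[rel["sample_id"].isin(md.index)]
    out: dict = {"target_gene": target_gene, "reference_gene": reference_gene,
                 "relative_expression": rel}
    for stratum in ("LE", "OB"):
        sub = rel[md.loc[rel["sample_id"], "maternal_group"].to_numpy()
                  == stratum]
        cls = md.loc[sub["sample_id"], "adiposity_class"].to_numpy()
        la = sub.loc[cls == "LA", "relative_expression"].to_numpy()
        ha = sub.loc[cls == "HA", "relative_expression"].to_numpy()
        if la.size and ha.size:
            out[f"rank_sum_p_{stratum}"] = rank_sum_test(la, ha)
    shared = [s for s in rel["sample_id"] if s in counts.columns
              and target_gene in counts.index]
    if len(shared) >= 3:
        logc = log_normalized(counts[shared]).loc[target_gene].to_numpy()
        rel_s = rel.set_index("sample_id").loc[shared,
                                               "relative_expression"].to_numpy()
        rho, p = spearman_corr(logc, rel_s)
        out["spearman_rho"] = rho
        out["spearman_p"] = p
    return out
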