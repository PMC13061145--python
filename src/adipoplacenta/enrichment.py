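"""Cross-stratum NAAG overlap, concordance classes, and gene-set ORA.

Genes retained in both maternal strata are the common NAAGs (CNAAGs),
classified concordant when their adiposity effect has the same direction in
lean and obese mothers and discordant otherwise.  Gene-set over-representation
is a one-sided hypergeometric test with Benjamini-Hochberg FDR across terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def derive_cnaags(naags_le: pd.DataFrame, naags_ob: pd.DataFrame) -> pd.DataFrame:
    """Intersect the two strata's NAAG tables and classify direction
    concordance.

    Inputs are indexed by gene_id with a ``direction`` column ("up"/"down").
    Output is sorted by gene_id with columns direction_le, direction_ob,
    concordance ("concordant" iff directions match).
    """
    common = sorted(set(naags_le.index) & set(naags_ob.index))
    rows = []
    for g in common:
        d_le = naags_le.loc[g, "direction"]
        d_ob = naags_ob.loc[g, "direction"]
        rows.append({
            "gene_id": g,
            "direction_le": d_le,
            "direction_ob": d_ob,
            "concordance": "concordant" if d_le == d_ob else "discordant",
        })
    return pd.DataFrame(rows, columns=["gene_id", "direction_le",
                                       "direction_ob", "concordance"]
                        ).set_index("gene_id")


def unique_naags(naags_le: pd.DataFrame,
                 naags_ob: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Genes retained in only one stratum: (LE-only, OB-only)."""
    le, ob = set(naags_le.index), set(naags_ob.index)
    return le - ob, ob - le


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving.

    Returns adjusted values in the input order; each output is >= its raw p
    and the sorted outputs are monotone non-decreasing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def go_enrichment(query, universe, gene_sets: dict[str, set[str]],
                  fdr_thr: float = 0.1) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    For a term of size K (after intersecting with the universe of size N) and
    a query of size n with overlap k, p = P(X >= k) for X hypergeometric.
    BH adjustment is applied across all tested terms; ``significant`` flags
    fdr < fdr_thr.  Terms with no members in the universe are skipped.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes not in universe (e.g. {extra})")
    N, n = len(universe), len(query)
    rows = []
    for term, members in gene_sets.items():
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "overlap": k, "term_size": K,
                     "query_size": n, "universe_size": N,
                     "p_hypergeometric": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term_id", "overlap", "term_size",
                                      "query_size", "universe_size",
                                      "p_hypergeometric"])
    if len(out):
        out["fdr_bh"] = bh_adjust(out["p_hypergeometric"].to_numpy())
        out["significant"] = out["fdr_bh"] < fdr_thr
        out = out.sort_values(["p_hypergeometric", "term_id"]).reset_index(
            drop=True)
    else:
        out["fdr_bh"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
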