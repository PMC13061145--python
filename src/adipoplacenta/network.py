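"""Interaction-network mapping, coexpression confirmation, hubs, enrichment.

A gene set is mapped onto a database edge list (node1, node2, combined_score).
Each database edge is tested for coexpression by the Pearson correlation of
the two genes' log-normalized expression within a sample group; edges with
|r| > 0.3 and p < .05 are "confirmed" (unconfirmed edges are retained for
context).  Hub genes strictly exceed the 90th empirical degree quantile.
Interaction enrichment of a gene set is assessed against a permutation null of
equal-size random draws from the universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import log_normalized
from .io import read_edges_tsv

DEFAULT_SCORE_MIN = 400.0
DEFAULT_R_THR = 0.3
DEFAULT_P_THR = 0.05
DEFAULT_HUB_Q = 0.90


def canonicalize_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Order endpoints lexicographically, drop self-loops, deduplicate
    (keeping the maximum combined score of duplicates)."""
    e = edges.copy()
    n1 = e["node1"].astype(str).to_numpy()
    n2 = e["node2"].astype(str).to_numpy()
    e["node1"] = np.minimum(n1, n2)
    e["node2"] = np.maximum(n1, n2)
    e = e[e["node1"] != e["node2"]]
    e = (e.groupby(["node1", "node2"], as_index=False)["combined_score"]
         .max().sort_values(["node1", "node2"]).reset_index(drop=True))
    return e


def load_string_edges(path: str,
                      score_min: float = DEFAULT_SCORE_MIN) -> pd.DataFrame:
    """Load a database edge list, keeping edges with combined_score >=
    score_min, canonicalized and deduplicated."""
    edges = read_edges_tsv(path)
    edges = edges[edges["combined_score"] >= score_min]
    return canonicalize_edges(edges)


def induced_edges(edges: pd.DataFrame, genes) -> pd.DataFrame:
    genes = set(genes)
    return edges[edges["node1"].isin(genes)
                 & edges["node2"].isin(genes)].reset_index(drop=True)


def pearson_confirm(x, y, r_thr: float = DEFAULT_R_THR,
                    p_thr: float = DEFAULT_P_THR) -> tuple[float, float, bool]:
    """Pearson r, two-sided t-test p (df = n - 2) and the confirmation flag
    (|r| > r_thr and p < p_thr) for one edge's expression vectors.

    Zero-variance input leaves r undefined: returns (nan, nan, False).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("correlation confirmation needs at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), bool(abs(r) > r_thr and p < p_thr)


def confirm_edges(edges: pd.DataFrame, counts: pd.DataFrame,
                  metadata: pd.DataFrame, group: str = "pooled",
                  r_thr: float = DEFAULT_R_THR,
                  p_thr: float = DEFAULT_P_THR) -> pd.DataFrame:
    """Annotate each edge with the Pearson correlation of its endpoints.

    Correlation is computed on log2(normalized count + 1) across the samples
    of ``group`` ("LE", "OB" or "pooled"); p comes from the two-sided t test
    with n - 2 degrees of freedom.  An edge is confirmed iff |r| > r_thr and
    p < p_thr; zero-variance endpoints leave r undefined and the edge
    unconfirmed.
    """
    md = metadata[metadata["sample_id"].isin(counts.columns)]
    if group != "pooled":
        md = md[md["maternal_group"] == group]
    samples = md["sample_id"].tolist()
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    expr = log_normalized(counts[samples])
    out = canonicalize_edges(edges)
    r_vals, p_vals, confirmed = [], [], []
    for a, b in zip(out["node1"], out["node2"]):
        if a not in expr.index or b not in expr.index:
            raise KeyError(f"edge endpoint missing from expression matrix: "
                           f"{a if a not in expr.index else b}")
        r, p, ok = pearson_confirm(expr.loc[a].to_numpy(),
                                   expr.loc[b].to_numpy(), r_thr, p_thr)
        r_vals.append(r)
        p_vals.append(p)
        confirmed.append(ok)
    out["pearson_r"] = r_vals
    out["pearson_p"] = p_vals
    out["confirmed"] = confirmed
    return out


def node_degrees(edges: pd.DataFrame, nodes=None) -> pd.Series:
    """Degree of every node in the edge list (optionally over a fixed node
    universe, so isolated nodes count with degree 0)."""
    import networkx as nx

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(zip(edges["node1"], edges["node2"]))
    deg = pd.Series(dict(g.degree()), dtype=int).sort_index()
    deg.index.name = "gene_id"
    return deg


def hub_genes(degrees: pd.Series, q: float = DEFAULT_HUB_Q) -> set[str]:
    """Nodes whose degree strictly exceeds the empirical q-quantile of the
    degree distribution (linear interpolation of order statistics)."""
    if len(degrees) == 0:
        raise ValueError("empty graph has no degree distribution")
    cut = float(np.quantile(degrees.to_numpy(float), q))
    return {str(n) for n, d in degrees.items() if d > cut}


def ppi_enrichment(gene_set, background_edges: pd.DataFrame, universe,
                   M: int = 999, seed: int = 0) -> tuple[float, int]:
    """Permutation test of interaction enrichment.

    The observed statistic is the number of background edges induced by the
    gene set; the null draws M random same-size gene sets from the universe.
    Returns (p, observed) with p = (1 + #{null >= observed}) / (M + 1).
    """
    if M < 100:
        raise ValueError("M must be at least 100")
    gene_set = set(gene_set)
    universe = sorted(set(universe))
    if not gene_set <= set(universe):
        raise ValueError("gene_set must be a subset of the universe")
    edges = canonicalize_edges(background_edges)
    # adjacency over universe for fast induced-edge counting
    index = {g: i for i, g in enumerate(universe)}
    a_idx = edges["node1"].map(index)
    b_idx = edges["node2"].map(index)
    ok = a_idx.notna() & b_idx.notna()
    a_arr = a_idx[ok].to_numpy(int)
    b_arr = b_idx[ok].to_numpy(int)

    def count_induced(members_mask):
        return int((members_mask[a_arr] & members_mask[b_arr]).sum())

    mask = np.zeros(len(universe), dtype=bool)
    mask[[index[g] for g in gene_set]] = True
    observed = count_induced(mask)
    rng = np.random.default_rng(seed)
    n = len(gene_set)
    ge = 0
    for _ in range(M):
        draw = rng.choice(len(universe), size=n, replace=False)
        m = np.zeros(len(universe), dtype=bool)
        m[draw] = True
        if count_induced(m) >= observed:
            ge += 1
    p = (1 + ge) / (M + 1)
    return float(p), observed


def confirmed_fraction(n_confirmed: int, n_edges: int) -> float:
    """Percentage of database edges confirmed by coexpression, to one
    decimal."""
    if n_edges == 0:
        raise ValueError("no edges; confirmed fraction undefined")
    return round(100.0 * n_confirmed / n_edges, 1)


def network_summary(annotated_edges: pd.DataFrame, gene_set, universe,
                    background_edges: pd.DataFrame, hub_q: float = DEFAULT_HUB_Q,
                    M: int = 999, seed: int = 0) -> dict:
    """Bundle degrees, hubs, confirmation counts and permutation enrichment."""
    deg = node_degrees(annotated_edges, nodes=sorted(set(gene_set)))
    hubs = hub_genes(deg, q=hub_q) if len(deg) else set()
    n_edges = int(len(annotated_edges))
    n_conf = int(annotated_edges["confirmed"].sum()) if n_edges else 0
    p, observed = ppi_enrichment(gene_set, background_edges, universe,
                                 M=M, seed=seed)
    return {
        "degrees": deg,
        "hubs": hubs,
        "n_edges": n_edges,
        "n_confirmed": n_conf,
        "confirmed_pct": confirmed_fraction(n_conf, n_edges) if n_edges else float("nan"),
        "enrichment_p": p,
        "observed_edges": observed,
    }
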