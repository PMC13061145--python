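"""Bootstrap-consistent differential expression and NAAG selection.

Within one maternal stratum the samples are resampled with replacement B times
(stratified within the LA and HA classes by default, preserving class sizes so
the adiposity factor is always estimable), the NB Wald test is rerun on every
resample, and a gene is retained as a neonatal adiposity-associated gene
(NAAG) when it is significant (p below the nominal threshold and linear fold
change beyond the FC threshold) with a consistent direction in at least the
required fraction of iterations.  Effect summaries are medians over
iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import nb_wald_de

DEFAULT_B = 100
DEFAULT_P_THR = 0.05
DEFAULT_FC_THR = 1.5      # linear fold change
DEFAULT_CONSISTENCY = 0.5


@dataclass
class BootstrapResult:
    """Iteration-level bootstrap output for one stratum.

    ``log2fc`` and ``p_value`` are (B x genes) arrays; non-converged fits are
    NaN.  ``converged`` marks which (iteration, gene) fits succeeded.
    """

    stratum: str
    gene_ids: list[str]
    log2fc: np.ndarray
    p_value: np.ndarray
    converged: np.ndarray
    B: int
    seed: int


def stratified_resample(metadata: pd.DataFrame, rng: np.random.Generator,
                        stratified: bool = True) -> pd.DataFrame:
    """Resample sample rows with replacement, within each adiposity class if
    ``stratified`` (preserving class sizes), otherwise from the pool."""
    if stratified:
        parts = []
        for _, grp in metadata.groupby("adiposity_class", sort=True):
            idx = rng.integers(0, len(grp), size=len(grp))
            parts.append(grp.iloc[idx])
        out = pd.concat(parts, ignore_index=True)
    else:
        idx = rng.integers(0, len(metadata), size=len(metadata))
        out = metadata.iloc[idx].reset_index(drop=True)
    return out


def bootstrap_de(counts: pd.DataFrame, metadata: pd.DataFrame, stratum: str,
                 B: int = DEFAULT_B, seed: int = 0,
                 stratified: bool = True) -> BootstrapResult:
    """Run the NB Wald DE test on B bootstrap resamples of one stratum.

    Resampled columns of the count matrix are duplicated as needed (a sample
    drawn twice contributes two columns).  Fully reproducible from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    md = metadata[(metadata["maternal_group"] == stratum)
                  & metadata["adiposity_class"].isin(["LA", "HA"])]
    md = md[md["sample_id"].isin(counts.columns)].reset_index(drop=True)
    if md["adiposity_class"].nunique() < 2:
        raise ValueError(f"stratum {stratum} lacks both adiposity classes")
    rng = np.random.default_rng(seed)
    gene_ids = list(counts.index)
    G = len(gene_ids)
    lfc = np.full((B, G), np.nan)
    pv = np.full((B, G), np.nan)
    conv = np.zeros((B, G), dtype=bool)
    for b in range(B):
        res_md = stratified_resample(md, rng, stratified=stratified)
        res_md = res_md.copy()
        cols = res_md["sample_id"].tolist()
        res_counts = counts[cols].copy()
        # uniquify duplicated sample columns
        new_ids = [f"{s}_b{b}_{i}" for i, s in enumerate(cols)]
        res_counts.columns = new_ids
        res_md["sample_id"] = new_ids
        de = nb_wald_de(res_counts, res_md, stratum=None)
        lfc[b] = de["log2fc"].to_numpy()
        pv[b] = de["p_value"].to_numpy()
        conv[b] = de["converged"].to_numpy()
    return BootstrapResult(stratum=stratum, gene_ids=gene_ids, log2fc=lfc,
                           p_value=pv, converged=conv, B=B, seed=seed)


def tally_bootstrap(result: BootstrapResult, p_thr: float = DEFAULT_P_THR,
                    fc_thr: float = DEFAULT_FC_THR,
                    medians_significant_only: bool = False) -> pd.DataFrame:
    """Count significant up/down iterations per gene and summarize medians.

    An iteration counts as significant-up for a gene when it converged,
    p < p_thr, |log2fc| > log2(fc_thr) and log2fc > 0 (significant-down
    analogously).  Medians are over converged iterations (optionally only the
    significant ones).
    """
    if not (0 < p_thr <= 1):
        raise ValueError("p_thr must lie in (0, 1]")
    if fc_thr < 1:
        raise ValueError("fc_thr is a linear fold change and must be >= 1")
    lfc_thr = math.log2(fc_thr)
    lfc, pv, conv = result.log2fc, result.p_value, result.converged
    with np.errstate(invalid="ignore"):
        sig = conv & (pv < p_thr) & (np.abs(lfc) > lfc_thr)
        up = sig & (lfc > 0)
        down = sig & (lfc < 0)
    n_up = up.sum(axis=0)
    n_down = down.sum(axis=0)
    if medians_significant_only:
        med_mask = sig
    else:
        med_mask = conv
    med_lfc = np.full(lfc.shape[1], np.nan)
    med_p = np.full(lfc.shape[1], np.nan)
    for j in range(lfc.shape[1]):
        m = med_mask[:, j]
        if m.any():
            med_lfc[j] = np.median(lfc[m, j])
            med_p[j] = np.median(pv[m, j])
    return pd.DataFrame({
        "B": result.B,
        "n_up_sig": n_up,
        "n_down_sig": n_down,
        "median_log2fc": med_lfc,
        "median_p": med_p,
        "n_converged": conv.sum(axis=0),
    }, index=pd.Index(result.gene_ids, name="gene_id"))


def select_naags(tallies: pd.DataFrame, consistency: float = DEFAULT_CONSISTENCY,
                 stratum: str | None = None) -> pd.DataFrame:
    """Retain genes whose majority direction is significant in at least
    ``consistency`` of all B iterations.

    A gene tied with n_up_sig == n_down_sig is rejected as directionally
    inconsistent even if either count alone clears the threshold.
    """
    if not (0 < consistency <= 1):
        raise ValueError("consistency must lie in (0, 1]")
    B = tallies["B"].to_numpy()
    n_up = tallies["n_up_sig"].to_numpy()
    n_down = tallies["n_down_sig"].to_numpy()
    frac = np.maximum(n_up, n_down) / B
    keep = (frac >= consistency) & (n_up != n_down)
    out = tallies.loc[keep].copy()
    out["direction"] = np.where(
        out["n_up_sig"] > out["n_down_sig"], "up", "down")
    out["consistency_fraction"] = np.maximum(
        out["n_up_sig"], out["n_down_sig"]) / out["B"]
    if stratum is not None:
        out["stratum"] = stratum
    cols = ["direction", "consistency_fraction", "median_log2fc", "median_p"]
    if stratum is not None:
        cols.append("stratum")
    return out[cols].sort_index()


def run_naag_selection(counts: pd.DataFrame, metadata: pd.DataFrame,
                       stratum: str, B: int = DEFAULT_B, seed: int = 0,
                       p_thr: float = DEFAULT_P_THR,
                       fc_thr: float = DEFAULT_FC_THR,
                       consistency: float = DEFAULT_CONSISTENCY,
                       stratified: bool = True,
                       medians_significant_only: bool = False) -> pd.DataFrame:
    """Bootstrap + tally + selection in one call; returns the NAAG table."""
    result = bootstrap_de(counts, metadata, stratum, B=B, seed=seed,
                          stratified=stratified)
    tallies = tally_bootstrap(result, p_thr=p_thr, fc_thr=fc_thr,
                              medians_significant_only=medians_significant_only)
    return select_naags(tallies, consistency=consistency, stratum=stratum)


def summarize_naag(tally_row: pd.Series) -> tuple[float, float]:
    """Median log2FC and median p for one gene's bootstrap tally."""
    if tally_row.get("n_converged", 1) == 0 or (
            isinstance(tally_row["median_log2fc"], float)
            and math.isnan(tally_row["median_log2fc"])):
        raise ValueError("no converged bootstrap iterations for this gene")
    return float(tally_row["median_log2fc"]), float(tally_row["median_p"])
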