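"""Per-stratum differential expression: filtering, QC, normalization, NB Wald test.

The engine approximates the standard count-based DE workflow: median-of-ratios
size factors, method-of-moments gene-wise NB dispersion (variance =
mu + alpha * mu^2), and a per-gene negative-binomial log-linear regression of
counts on neonatal adiposity (LA vs HA) adjusted for child sex, fit by
iteratively reweighted least squares vectorized across genes.  Significance is
a Wald z-test on the adiposity coefficient.  No empirical-Bayes dispersion
shrinkage, independent filtering or outlier replacement is applied by default:
robustness is delegated to the bootstrap-consistency layer built on top.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
_ETA_CLIP = 30.0
_BETA_DIVERGED = 20.0


def filter_protein_coding(counts: pd.DataFrame, coding_list) -> pd.DataFrame:
    """Keep rows whose gene id is in the coding list, preserving order."""
    coding = set(coding_list)
    keep = [g for g in counts.index if g in coding]
    if not keep:
        raise ValueError("no genes in the count matrix match the coding list")
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth normalization.

    For every gene positive in all samples, compute the ratio of each sample's
    count to the gene's geometric mean; the sample's size factor is the median
    of those ratios.
    """
    vals = counts.to_numpy(float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "cannot compute median-of-ratios size factors")
    logv = np.log(vals[all_pos])
    log_geo = logv.mean(axis=1, keepdims=True)
    ratios = np.exp(logv - log_geo)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame,
                      sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts / sf.reindex(counts.columns).to_numpy()


def log_normalized(counts: pd.DataFrame,
                   sf: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalized count + 1), the transform used for PCA and correlation."""
    return np.log2(normalized_counts(counts, sf) + 1.0)


def estimate_dispersion(counts: pd.DataFrame, sf: pd.Series | None = None,
                        shrink: bool = False) -> pd.DataFrame:
    """Method-of-moments gene-wise NB dispersion on normalized counts.

    alpha_g = max(floor, (s^2_g - m_g) / m_g^2); genes with zero mean are set
    to the floor and flagged.  With ``shrink=True`` estimates are pulled
    halfway (in log space) toward a fitted a0 + a1/mean trend.
    """
    if len(counts.columns) < 2:
        raise ValueError("dispersion estimation needs at least 2 samples")
    norm = normalized_counts(counts, sf).to_numpy(float)
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    zero_mean = m <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / np.square(m)
    alpha = np.where(zero_mean, DISPERSION_FLOOR, alpha)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    if shrink:
        ok = (~zero_mean) & (alpha > DISPERSION_FLOOR)
        if ok.sum() >= 10:
            A = np.column_stack([np.ones(ok.sum()), 1.0 / m[ok]])
            coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
            trend = np.maximum(coef[0] + coef[1] / np.maximum(m, 1e-12),
                               DISPERSION_FLOOR)
            alpha = np.where(ok, np.exp(0.5 * (np.log(alpha) + np.log(trend))),
                             alpha)
    return pd.DataFrame({"alpha": alpha, "zero_mean": zero_mean},
                        index=counts.index)


def pca_outliers(counts: pd.DataFrame, k: float = 5.0,
                 n_top: int = 500) -> list[str]:
    """Flag outlier samples in the PC1-PC2 plane of log-normalized expression.

    The top ``n_top`` most variable genes are projected onto their first two
    principal components; a sample is flagged when its MAD-scaled robust
    distance from the coordinate-wise median exceeds ``k``.
    """
    if counts.shape[1] < 4:
        raise ValueError("PCA outlier screening needs at least 4 samples")
    if not math.isfinite(k):
        return []
    logn = log_normalized(counts).to_numpy(float)
    if n_top > logn.shape[0]:
        logger.warning("n_top=%d exceeds gene count %d; clamping",
                       n_top, logn.shape[0])
        n_top = logn.shape[0]
    var = logn.var(axis=1)
    top = np.argsort(var)[::-1][:n_top]
    X = logn[top].T                       # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = X @ vt[:2].T                 # samples x 2
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * 1.4826
    z = np.where(mad > 0, (scores - med) / np.where(mad > 0, mad, 1.0), 0.0)
    dist = np.sqrt((z ** 2).sum(axis=1))
    return [str(c) for c, d in zip(counts.columns, dist) if d > k]


# ---------------------------------------------------------------------------
# Vectorized NB IRLS Wald test
# ---------------------------------------------------------------------------

def _nb_deviance(y, mu, alpha):
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    term2 = (y + 1.0 / alpha) * (np.log1p(alpha * mu) - np.log1p(alpha * y))
    return 2.0 * (term1 + term2).sum(axis=1)


def nb_irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
            alpha: np.ndarray, tol: float = IRLS_TOL,
            max_iter: int = IRLS_MAX_ITER):
    """Fit G independent NB log-link regressions sharing a design matrix.

    Parameters
    ----------
    y : (G, n) counts;  X : (n, p) design;  offset : (n,) log size factors;
    alpha : (G,) NB dispersions.

    Returns
    -------
    beta : (G, p) coefficients; cov : (G, p, p) inverse Fisher information;
    converged : (G,) bool.
    """
    G, n = y.shape
    p = X.shape[1]
    alpha = alpha[:, None]
    # OLS init on log counts
    pinv = np.linalg.pinv(X)
    beta = (np.log(y + 0.5) - offset[None, :]) @ pinv.T
    dev = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = eta - offset[None, :] + (y - mu) / mu
        XtWX = np.einsum("gn,np,nq->gpq", w, X, X) + ridge
        XtWz = np.einsum("gn,np->gp", w * z, X)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = (np.linalg.pinv(XtWX) @ XtWz[..., None])[..., 0]
        new_beta = np.where(active[:, None], new_beta, beta)
        eta2 = np.clip(new_beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        new_dev = _nb_deviance(y, np.exp(eta2), alpha)
        done = np.abs(new_dev - dev) < tol * (np.abs(new_dev) + 0.1)
        converged |= active & done & np.isfinite(new_dev)
        active = active & ~done
        beta, dev = new_beta, new_dev
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("gn,np,nq->gpq", w, X, X) + ridge
    cov = np.linalg.pinv(XtWX)
    diverged = (np.abs(beta) > _BETA_DIVERGED).any(axis=1) | ~np.isfinite(
        beta).all(axis=1)
    converged &= ~diverged
    return beta, cov, converged


def build_design(metadata: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix (intercept, adiposity HA=1, sex M=1; female reference).

    The sex column is dropped with a warning if only one level is present in
    the (sub)sample, which can happen in bootstrap resamples.
    """
    adip = metadata["adiposity_class"].map({"LA": 0.0, "HA": 1.0})
    if adip.isna().any():
        raise ValueError("adiposity_class must be LA or HA for DE")
    if adip.nunique() < 2:
        raise ValueError("stratum must contain both LA and HA samples")
    cols = [np.ones(len(metadata)), adip.to_numpy()]
    names = ["intercept", "adiposity"]
    sex = (metadata["sex"] == "M").to_numpy(float)
    if np.unique(sex).size > 1:
        cols.append(sex)
        names.append("sex")
    else:
        logger.warning("single sex level present; dropping sex covariate")
    return np.column_stack(cols), names


def nb_wald_de(counts: pd.DataFrame, metadata: pd.DataFrame,
               stratum: str | None = None,
               dispersion: pd.Series | np.ndarray | None = None,
               shrink_dispersion: bool = False) -> pd.DataFrame:
    """NB Wald differential-expression test of adiposity within one stratum.

    Subsets to the requested maternal stratum's LA/HA samples, computes size
    factors and dispersions on that subset (unless supplied), fits the NB
    regression per gene, and reports the adiposity effect as log2 fold change
    (HA vs LA) with its Wald z statistic and two-sided normal p-value.
    Non-converged genes carry NaN statistics and ``converged=False``.
    """
    md = metadata.copy()
    if stratum is not None:
        md = md[md["maternal_group"] == stratum]
    md = md[md["adiposity_class"].isin(["LA", "HA"])]
    md = md[md["sample_id"].isin(counts.columns)]
    sub = counts[md["sample_id"].tolist()]
    X, names = build_design(md)
    sf = size_factors(sub)
    if dispersion is None:
        alpha = estimate_dispersion(sub, sf, shrink=shrink_dispersion)[
            "alpha"].to_numpy()
    else:
        alpha = np.asarray(dispersion, float)
        if alpha.ndim == 0:
            alpha = np.full(len(sub), float(alpha))
    y = sub.to_numpy(float)
    offset = np.log(sf.to_numpy())
    beta, cov, converged = nb_irls(y, X, offset, np.maximum(alpha,
                                                            DISPERSION_FLOOR))
    j = names.index("adiposity")
    b = beta[:, j]
    se_nat = np.sqrt(np.maximum(cov[:, j, j], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b / se_nat
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ln2 = math.log(2.0)
    out = pd.DataFrame({
        "log2fc": b / ln2,
        "se": se_nat / ln2,
        "wald_stat": z,
        "p_value": pvals,
        "converged": converged,
    }, index=sub.index)
    out.loc[~out["converged"], ["log2fc", "se", "wald_stat", "p_value"]] = np.nan
    out.index.name = "gene_id"
    return out
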