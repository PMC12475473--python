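"""Hurdle differential expression with cellular detection as covariate,
BH-FDR, ratio-based cluster markers, and aging-DEG selection.

The per-gene model has two parts, in the spirit of MAST: a logistic
regression of the detection indicator (count > 0) on group plus the
cellular detection rate (CDR, the fraction of measured genes a cell
detects), and a Gaussian linear model of log-normalized expression on the
same design among detected cells only. Each part contributes a
likelihood-ratio chi-square for dropping the group term; the parts are
independent under the hurdle factorization, so the statistics add and the
combined test has df = 2 (df = 1 when one part is degenerate, e.g. a gene
detected in every cell).

log2FC is defined as the difference of group means of log2-scale
normalized expression including zeros — conventions differ across tools,
so this one is fixed explicitly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

logger = logging.getLogger("striaging")

_LN2 = np.log(2.0)


def detection_rate(counts: CountMatrix) -> np.ndarray:
    """Per-cell fraction of measured genes with count > 0 (the CDR)."""
    if counts.n_genes == 0:
        raise ValueError("empty matrix")
    return np.asarray((counts.matrix > 0).sum(axis=1)).ravel() / counts.n_genes


def _logit_nll(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> float | None:
    """Maximized negative log-likelihood of a logistic regression via
    Newton-IRLS with a small ridge for separation safety. Returns None if
    the response is constant."""
    if y.min() == y.max():
        return None
    n, p = X.shape
    beta = np.zeros(p)
    ridge = 1e-8
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return -ll


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def hurdle_de(
    norm_matrix: CountMatrix,
    group_labels,
    test_group: str | None = None,
    cdr: np.ndarray | None = None,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Two-part hurdle DE between two groups of cells.

    Parameters
    ----------
    norm_matrix
        Log-normalized expression (zeros mark undetected genes).
    group_labels
        One label per cell; exactly two distinct values.
    test_group
        The group whose elevation yields positive log2fc; defaults to the
        lexicographically larger label.
    cdr
        Per-cell detection rate covariate; computed from the nonzero
        pattern of ``norm_matrix`` when omitted.

    Returns a DataFrame indexed by gene with columns log2fc, pct_in,
    pct_out, ratio (pct_in/pct_out with add-one smoothing when pct_out is
    zero), p_value, fdr, direction, degenerate.
    """
    groups = pd.Series(np.asarray(group_labels), index=norm_matrix.cell_ids)
    uniq = sorted(groups.unique())
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if test_group is None:
        test_group = uniq[-1]
    if test_group not in uniq:
        raise ValueError(f"test_group {test_group!r} not among {uniq}")
    is_test = (groups == test_group).to_numpy()
    n_in, n_out = int(is_test.sum()), int((~is_test).sum())
    if min(n_in, n_out) < min_cells:
        raise ValueError(f"each group needs >= {min_cells} cells (got {n_in}, {n_out})")

    dense = norm_matrix.to_dense()
    detected = dense > 0
    if cdr is None:
        cdr = detected.mean(axis=1)
    cdr = np.asarray(cdr, dtype=float)
    cdr_c = cdr - cdr.mean()

    X_full = np.column_stack([np.ones(dense.shape[0]), is_test.astype(float), cdr_c])
    X_red = X_full[:, [0, 2]]

    expr2 = dense / _LN2  # log2 scale including zeros
    log2fc = expr2[is_test].mean(axis=0) - expr2[~is_test].mean(axis=0)
    pct_in = detected[is_test].mean(axis=0)
    pct_out = detected[~is_test].mean(axis=0)
    eps = 1.0 / (n_out + 1)
    ratio = pct_in / np.where(pct_out > 0, pct_out, eps)

    n_genes = dense.shape[1]
    pvals = np.ones(n_genes)
    degenerate = np.zeros(n_genes, dtype=bool)
    for g in range(n_genes):
        z = detected[:, g].astype(float)
        chi2_stat, df = 0.0, 0
        nll_full = _logit_nll(X_full, z)
        if nll_full is not None:
            nll_red = _logit_nll(X_red, z)
            chi2_stat += max(0.0, 2.0 * (nll_red - nll_full))
            df += 1
        det = detected[:, g]
        n_det = int(det.sum())
        if n_det > X_full.shape[1] + 1:
            y = dense[det, g]
            if y.std() > 0:
                rss_full = _ols_rss(X_full[det], y)
                rss_red = _ols_rss(X_red[det], y)
                if rss_full > 0:
                    chi2_stat += max(0.0, n_det * np.log(rss_red / rss_full))
                    df += 1
        if df == 0:
            degenerate[g] = True  # e.g. detected nowhere: p = 1, no effect
            continue
        pvals[g] = stats.chi2.sf(chi2_stat, df)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "ratio": ratio,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "direction": np.where(log2fc >= 0, "up", "down"),
            "degenerate": degenerate,
        },
        index=norm_matrix.gene_ids,
    )
    out.loc[degenerate, ["log2fc"]] = 0.0
    out.loc[degenerate, "direction"] = "up"
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_cluster_markers(
    norm_matrix: CountMatrix,
    clusters,
    ratio_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    top_n: int = 10,
    cdr: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-vs-rest hurdle DE per cluster; keep genes whose in/out detection
    ratio is >= ``ratio_threshold`` (inclusive) at FDR < ``fdr_threshold``;
    rank by FDR then ratio and return the top ``top_n`` per cluster."""
    clusters = pd.Series(np.asarray(clusters), index=norm_matrix.cell_ids)
    ids = sorted(clusters.unique())
    if len(ids) < 2:
        raise ValueError("marker selection needs at least 2 clusters")
    frames = []
    for cid in ids:
        labels = np.where(clusters == cid, "in", "out")
        de = hurdle_de(norm_matrix, labels, test_group="in", cdr=cdr)
        keep = de[(de["ratio"] >= ratio_threshold) & (de["fdr"] < fdr_threshold)]
        if keep.empty:
            logger.warning("cluster %s: no gene passes the marker criteria", cid)
            continue
        keep = keep.sort_values(["fdr", "ratio"], ascending=[True, False]).head(top_n)
        keep = keep.reset_index(names="gene")
        keep.insert(0, "cluster", str(cid))
        frames.append(keep)
    if not frames:
        return pd.DataFrame(columns=["cluster", "gene", "log2fc", "pct_in", "pct_out",
                                     "ratio", "p_value", "fdr", "direction", "degenerate"])
    return pd.concat(frames, ignore_index=True)


def select_aging_degs(
    de_result: pd.DataFrame,
    log2fc_min: float = 0.25,
    fdr_max: float = 0.05,
    top_k: int = 20,
) -> tuple[list[str], list[str]]:
    """Aging DEGs: |log2FC| strictly > 0.25 and FDR < 0.05; the top-k list
    (for module scoring) ranks by FDR, ties broken by |log2FC|."""
    if de_result.empty:
        return [], []
    hits = de_result[(de_result["log2fc"].abs() > log2fc_min)
                     & (de_result["fdr"] < fdr_max)].copy()
    hits["_abs"] = hits["log2fc"].abs()
    hits = hits.sort_values(["fdr", "_abs"], ascending=[True, False])
    all_genes = list(hits.index)
    return all_genes, all_genes[:top_k]
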