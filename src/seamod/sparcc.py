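"""Compositional correlation inference (SparCC-style).

Estimates ASV-ASV correlations from compositional count data via the
variance of log-ratios and the basis-variance approximation, with
iterative exclusion of strongly correlated pairs, a column-permutation
bootstrap for p-values and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import stage_rng

__all__ = [
    "CorrelationResult",
    "estimate_fractions",
    "basis_variances",
    "sparcc_correlations",
    "sparcc",
    "bootstrap_pvalues",
    "adjust_pvalues",
    "significant_edges",
]


@dataclass
class CorrelationResult:
    """Correlations with raw and adjusted bootstrap p-values for one subset."""

    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    subset_label: str = ""


def estimate_fractions(counts, mode: str = "pseudocount", k: int = 20, seed: int = 0):
    """Per-sample component fractions from counts.

    ``pseudocount``: deterministic ``(x + 1) / sum(x + 1)``.
    ``dirichlet``: mean of ``k`` posterior Dirichlet(x + 1) draws; converges
    to the pseudocount values as ``k`` grows.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if mode == "pseudocount":
        y = x + 1.0
        return y / y.sum(axis=1, keepdims=True)
    if mode == "dirichlet":
        rng = stage_rng(seed, "fractions")
        draws = np.stack([
            np.apply_along_axis(lambda row: rng.dirichlet(row + 1.0), 1, x)
            for _ in range(k)
        ])
        return draws.mean(axis=0)
    raise ValueError(f"unknown fraction mode: {mode!r}")


def _variation_matrix(fractions):
    """V[i, j] = var over samples of log(f_i / f_j)."""
    logf = np.log(fractions)
    va = logf.var(axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = va[:, None] + va[None, :] - 2.0 * cov
    np.fill_diagonal(v, 0.0)
    return np.maximum(v, 0.0)


def basis_variances(v, m=None, t=None):
    """Solve the basis-variance linear system ``M w = t``.

    With no exclusions, ``M`` has ``D - 1`` on the diagonal and 1 off it,
    and ``t_i = sum_j V_ij``. Callers performing pair exclusion pass
    adjusted ``m`` and ``t``.
    """
    v = np.asarray(v, dtype=float)
    d = v.shape[0]
    if d < 3:
        raise ValueError("basis variance system needs at least 3 components")
    if t is None:
        t = v.sum(axis=1)
    if m is None:
        m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    return np.linalg.solve(m, t)


def _correlations_from_basis(v, w):
    with np.errstate(invalid="ignore", divide="ignore"):
        # negative basis variances can occur when the approximation breaks
        # down; the affected correlations are zeroed below
        denom = 2.0 * np.sqrt(np.outer(w, w))
        r = (w[:, None] + w[None, :] - v) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def sparcc_correlations(
    fractions,
    exclusion_threshold: float = 0.1,
    n_exclusion_rounds: int = 10,
):
    """Correlation matrix from one fraction estimate.

    Repeatedly removes the most strongly correlated pair (|r| above
    ``exclusion_threshold``) from the basis-variance system, which
    counteracts the dilution of the basis approximation by genuinely
    correlated components. Requires at least 4 components.
    """
    f = np.asarray(fractions, dtype=float)
    d = f.shape[1]
    if d < 4:
        raise ValueError(
            "sparcc needs >= 4 ASVs; for fewer, compare log-ratio variances directly"
        )
    v = _variation_matrix(f)
    t = v.sum(axis=1)
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    w = basis_variances(v, m, t)
    r = _correlations_from_basis(v, w)
    excluded = np.zeros((d, d), dtype=bool)
    np.fill_diagonal(excluded, True)
    for _ in range(n_exclusion_rounds):
        masked = np.where(excluded, 0.0, np.abs(r))
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t[i] -= v[i, j]
        t[j] -= v[i, j]
        try:
            w = basis_variances(v, m, t)
        except np.linalg.LinAlgError:
            break
        r = _correlations_from_basis(v, w)
    return r


def sparcc(
    counts,
    mode: str = "pseudocount",
    n_inner_iter: int = 20,
    exclusion_threshold: float = 0.1,
    n_exclusion_rounds: int = 10,
    seed: int = 0,
):
    """Correlations from counts; in dirichlet mode, the median over
    ``n_inner_iter`` posterior resamplings."""
    if mode == "pseudocount":
        f = estimate_fractions(counts, "pseudocount")
        return sparcc_correlations(f, exclusion_threshold, n_exclusion_rounds)
    rs = []
    for it in range(n_inner_iter):
        f = estimate_fractions(counts, "dirichlet", k=1, seed=stage_rng(seed, "inner", it).integers(2**31))
        rs.append(sparcc_correlations(f, exclusion_threshold, n_exclusion_rounds))
    return np.median(np.stack(rs), axis=0)


def bootstrap_pvalues(
    counts,
    n_boot: int = 999,
    seed: int = 0,
    mode: str = "pseudocount",
    exclusion_threshold: float = 0.1,
    n_exclusion_rounds: int = 10,
):
    """Bootstrap p-values by independently permuting each ASV across samples.

    ``p_ij`` is the plain proportion of shuffles whose ``|r|`` is at least
    ``|r_obs|`` (two-sided; no add-one correction, so the minimum is 0).

    Returns ``(r_obs, p_raw)`` as arrays.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(counts, dtype=np.int64)
    rng = stage_rng(seed, "bootstrap")
    r_obs = sparcc(x, mode=mode, exclusion_threshold=exclusion_threshold,
                   n_exclusion_rounds=n_exclusion_rounds, seed=seed)
    abs_obs = np.abs(r_obs)
    hits = np.zeros_like(r_obs)
    n, d = x.shape
    for _ in range(n_boot):
        shuffled = np.empty_like(x)
        for j in range(d):
            shuffled[:, j] = x[rng.permutation(n), j]
        r_b = sparcc(shuffled, mode=mode, exclusion_threshold=exclusion_threshold,
                     n_exclusion_rounds=n_exclusion_rounds, seed=seed)
        hits += np.abs(r_b) >= abs_obs
    return r_obs, hits / n_boot


def adjust_pvalues(p_raw, method: str = "fdr_bh"):
    """Benjamini-Hochberg adjustment over the upper triangle; symmetric output."""
    p = np.asarray(p_raw, dtype=float)
    iu = np.triu_indices(p.shape[0], k=1)
    adj = np.ones_like(p)
    if iu[0].size:
        _, p_adj, _, _ = multipletests(p[iu], method=method)
        adj[iu] = p_adj
        adj[(iu[1], iu[0])] = p_adj
    np.fill_diagonal(adj, 0.0)
    return adj


def sparcc_with_pvalues(
    counts: pd.DataFrame,
    n_boot: int = 999,
    seed: int = 0,
    subset_label: str = "",
    **kwargs,
) -> CorrelationResult:
    """Full inference for one data subset: r, raw and BH-adjusted p-values."""
    r, p_raw = bootstrap_pvalues(counts.to_numpy(), n_boot=n_boot, seed=seed, **kwargs)
    p_adj = adjust_pvalues(p_raw)
    ids = list(counts.columns)
    return CorrelationResult(
        r=pd.DataFrame(r, index=ids, columns=ids),
        p_raw=pd.DataFrame(p_raw, index=ids, columns=ids),
        p_adj=pd.DataFrame(p_adj, index=ids, columns=ids),
        subset_label=subset_label,
    )


def significant_edges(
    result: CorrelationResult,
    r_min: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Positive edges with ``r >= r_min`` (inclusive) and ``p_adj <= alpha``.

    Negative associations are never reported.
    """
    if not (0.0 < r_min <= 1.0):
        raise ValueError("r_min must be in (0, 1]")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    ids = list(result.r.index)
    r = result.r.to_numpy()
    p_raw = result.p_raw.to_numpy()
    p_adj = result.p_adj.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if r[i, j] >= r_min and p_adj[i, j] <= alpha:
                rows.append((ids[i], ids[j], r[i, j], p_raw[i, j], p_adj[i, j],
                             result.subset_label))
    return pd.DataFrame(rows, columns=["asv_i", "asv_j", "r", "p_raw", "p_adj", "subset"])
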