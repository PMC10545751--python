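"""Count-table preprocessing and diversity.

Abundance filtering, rarefaction, richness / inverse-Simpson ENS,
normalized weighted UniFrac with WPGMA linkage, and abundance-weighted
environmental niche summaries per module.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd
import skbio
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._util import stage_rng

__all__ = [
    "abundance_filter",
    "rarefy",
    "richness",
    "ens_inverse_simpson",
    "weighted_unifrac",
    "unifrac_matrix",
    "wpgma",
    "module_env_preferences",
]

#: thresholds of the prevalence/abundance filter, exposed for configs
FILTER_DEFAULTS = {
    "global_rel": 1e-5,      # > 0.001 % of all reads in the table
    "single_rel": 0.01,      # criterion 1: > 1 % in at least one sample
    "prev_rel": 0.001,       # criterion 2: > 0.1 % ...
    "prev_frac": 0.02,       # ... in at least 2 % of samples
    "presence_frac": 0.05,   # criterion 3: present in at least 5 % of samples
}


def abundance_filter(
    counts: pd.DataFrame,
    global_rel: float = FILTER_DEFAULTS["global_rel"],
    single_rel: float = FILTER_DEFAULTS["single_rel"],
    prev_rel: float = FILTER_DEFAULTS["prev_rel"],
    prev_frac: float = FILTER_DEFAULTS["prev_frac"],
    presence_frac: float = FILTER_DEFAULTS["presence_frac"],
) -> pd.DataFrame:
    """Drop rare ASVs likely to yield spurious correlations.

    An ASV is kept iff its share of all reads exceeds ``global_rel``
    (strict) AND it satisfies at least one of:

    1. relative abundance > ``single_rel`` in at least one sample;
    2. relative abundance > ``prev_rel`` in at least ``prev_frac`` of samples;
    3. present (any count) in at least ``presence_frac`` of samples.

    Fraction-of-samples criteria are inclusive (>=) and evaluated on the
    raw sample count without rounding. Apply per ocean basin by calling
    once per basin subset.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count table")
    x = counts.to_numpy(dtype=float)
    total = x.sum()
    if total == 0:
        raise ValueError("count table contains no reads")
    n = x.shape[0]
    rel = x / np.maximum(x.sum(axis=1, keepdims=True), 1.0)

    global_ok = x.sum(axis=0) / total > global_rel
    c1 = (rel > single_rel).any(axis=0)
    c2 = (rel > prev_rel).sum(axis=0) >= prev_frac * n
    c3 = (x > 0).sum(axis=0) >= presence_frac * n
    keep = global_ok & (c1 | c2 | c3)
    return counts.loc[:, counts.columns[keep]]


def rarefy(counts: pd.DataFrame, depth: int = 8000, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = stage_rng(seed, "rarefy", depth)
    totals = counts.sum(axis=1)
    kept = counts.loc[totals >= depth]
    out = np.empty(kept.shape, dtype=np.int64)
    arr = kept.to_numpy(dtype=np.int64)
    d = arr.shape[1]
    for i in range(arr.shape[0]):
        row = arr[i]
        if row.sum() == depth:
            out[i] = row
            continue
        pool = np.repeat(np.arange(d), row)
        picked = rng.permutation(pool)[:depth]
        out[i] = np.bincount(picked, minlength=d)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def richness(counts: pd.DataFrame) -> pd.Series:
    """Number of ASVs with a positive count, per sample."""
    return (counts > 0).sum(axis=1).rename("richness")


def ens_inverse_simpson(counts: pd.DataFrame) -> pd.Series:
    """Effective number of species: ``1 / sum(p_i^2)`` per sample."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:3]
        raise ValueError(f"ENS undefined for all-zero sample(s): {bad}")
    p = counts.div(totals, axis=0)
    return (1.0 / (p**2).sum(axis=1)).rename("ens")


# ---------------------------------------------------------------------------
# weighted UniFrac + WPGMA


def _as_tree(tree):
    if isinstance(tree, skbio.TreeNode):
        return tree
    return skbio.TreeNode.read(_io.StringIO(str(tree)))


def _branch_masses(tree, profile, label):
    """Per-node subtree mass for a tip profile; validates tip names."""
    masses = {}
    tip_names = set()
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            masses[id(node)] = float(profile.get(node.name, 0.0))
            tip_names.add(node.name)
        else:
            masses[id(node)] = sum(masses[id(c)] for c in node.children)
    missing = [k for k, v in profile.items() if v > 0 and k not in tip_names]
    if missing:
        raise KeyError(f"tip '{missing[0]}' from profile {label} not found in tree")
    return masses


def weighted_unifrac(profile_a, profile_b, tree, normalized: bool = True) -> float:
    """Weighted UniFrac distance between two relative-abundance profiles.

    Both profiles (mappings tip name -> abundance) are renormalized to
    sum to one. The unnormalized value is the branch-length-weighted L1
    distance between the two subtree-mass functions; the normalized form
    divides by ``sum_b l_b (m_a(b) + m_b(b))`` and lies in [0, 1].
    """
    tree = _as_tree(tree)
    pa = dict(profile_a)
    pb = dict(profile_b)
    for label, p in (("a", pa), ("b", pb)):
        s = sum(p.values())
        if s <= 0:
            raise ValueError(f"profile {label} has zero total abundance")
        for k in p:
            p[k] /= s
    ma = _branch_masses(tree, pa, "a")
    mb = _branch_masses(tree, pb, "b")
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        num += length * abs(ma[id(node)] - mb[id(node)])
        den += length * (ma[id(node)] + mb[id(node)])
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


def unifrac_matrix(profiles: pd.DataFrame, tree, normalized: bool = True) -> pd.DataFrame:
    """All pairwise weighted UniFrac distances (profiles: rows x tips)."""
    tree = _as_tree(tree)
    labels = list(profiles.index)
    d = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d[i, j] = d[j, i] = weighted_unifrac(
                profiles.iloc[i].to_dict(), profiles.iloc[j].to_dict(), tree, normalized
            )
    return pd.DataFrame(d, index=labels, columns=labels)


def wpgma(dist: pd.DataFrame):
    """WPGMA (McQuitty) linkage on a symmetric distance matrix.

    Returns ``(Z, labels)`` with ``Z`` in scipy linkage format; the merge
    height of two clusters is the unweighted average of the children's
    distances.
    """
    labels = list(dist.index)
    z = linkage(squareform(dist.to_numpy(dtype=float), checks=True), method="weighted")
    return z, labels


# ---------------------------------------------------------------------------
# niche summaries


def module_env_preferences(
    module_abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    parameters,
):
    """Abundance-weighted environmental preferences per module.

    For each (module, parameter): the mean of the parameter over samples
    weighted by that module's abundance in each sample. Means are then
    normalized by the total over modules for each parameter and
    standardized to z-scores across modules (population sd; a zero sd
    yields z = 0). Modules with zero total abundance are excluded and
    reported separately.

    Returns ``(means, zscores, excluded)``.
    """
    parameters = list(parameters)
    meta = metadata.loc[module_abundance.index, parameters].to_numpy(dtype=float)
    w = module_abundance.to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("module abundances must be >= 0")
    wsum = w.sum(axis=0)
    excluded = [m for m, s in zip(module_abundance.columns, wsum) if s == 0]
    valid = wsum > 0
    means = (w.T @ meta) / np.where(wsum[:, None] > 0, wsum[:, None], np.nan)
    means_df = pd.DataFrame(means, index=module_abundance.columns, columns=parameters)

    v = means_df.loc[valid]
    colsum = v.sum(axis=0)
    norm = v / colsum.replace(0.0, np.nan)
    sd = norm.std(axis=0, ddof=0)
    z = (norm - norm.mean(axis=0)) / sd.replace(0.0, np.nan)
    z = z.fillna(0.0)
    return means_df, z, excluded
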