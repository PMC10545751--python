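"""Pairwise community-assembly mechanism classification.

Phylogenetic turnover (abundance-weighted beta mean nearest taxon
distance and its tip-shuffle z-score) decides selection; where no
phylogenetic signal exists, an abundance-adjusted Raup-Crick index on
Bray-Curtis distances decides dispersal; the residual class is drift.

Decision rule: z > +2 -> heterogeneous selection; z < -2 -> homogeneous
selection; otherwise RC > 0.95 -> dispersal limitation, RC < -0.95 ->
homogenizing dispersal, else drift.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from ._util import stage_rng

__all__ = [
    "LABELS",
    "bmntd",
    "bnti",
    "rc_bray",
    "classify",
    "within_group_pairs",
    "pairwise_mechanisms",
    "mechanism_fractions",
]

LABELS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def bmntd(pa, pb, dmat) -> float:
    """Abundance-weighted beta mean nearest taxon distance.

    ``0.5 * (sum_i pa_i * min_j D_ij + sum_j pb_j * min_i D_ij)`` where i
    runs over taxa present in community a and j over taxa present in b;
    abundances are renormalized over each community's support. Shared
    taxa contribute their (zero) self-distance, so identical communities
    score 0.
    """
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    d = np.asarray(dmat, dtype=float)
    ia = np.nonzero(pa > 0)[0]
    ib = np.nonzero(pb > 0)[0]
    if ia.size == 0 or ib.size == 0:
        raise ValueError("community with zero total abundance")
    wa = pa[ia] / pa[ia].sum()
    wb = pb[ib] / pb[ib].sum()
    sub = d[np.ix_(ia, ib)]
    return float(0.5 * ((wa * sub.min(axis=1)).sum() + (wb * sub.min(axis=0)).sum()))


def bnti(pa, pb, dmat, n_null: int = 999, seed=0) -> float:
    """z-score of the observed bMNTD against a tip-label-shuffle null.

    Each null permutes the taxon labels of the distance matrix (taxa
    identities on the tree are shuffled while abundances stay in place).
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    d = np.asarray(dmat, dtype=float)
    obs = bmntd(pa, pb, d)
    ia = np.nonzero(pa > 0)[0]
    ib = np.nonzero(pb > 0)[0]
    wa = pa[ia] / pa[ia].sum()
    wb = pb[ib] / pb[ib].sum()
    n = d.shape[0]
    null = np.empty(n_null)
    for k in range(n_null):
        perm = rng.permutation(n)
        sub = d[np.ix_(perm[ia], perm[ib])]
        null[k] = 0.5 * ((wa * sub.min(axis=1)).sum() + (wb * sub.min(axis=0)).sum())
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "null bMNTD distribution has zero spread; the tree or communities "
            "are degenerate (all distances equal?)"
        )
    return float((obs - null.mean()) / sd)


def _weighted_sample_without_replacement(k, weights, rng):
    """Sequential weighted sampling of k distinct indices."""
    w = np.asarray(weights, dtype=float).copy()
    chosen = []
    for _ in range(k):
        p = w / w.sum()
        i = rng.choice(w.size, p=p)
        chosen.append(i)
        w[i] = 0.0
    return np.array(chosen, dtype=int)


def _null_assembly(n_individuals, n_species, pool_freq, pool_ab, rng):
    s = pool_freq.size
    idx = _weighted_sample_without_replacement(n_species, pool_freq, rng)
    vec = np.zeros(s)
    vec[idx] = 1.0
    remaining = int(n_individuals) - n_species
    if remaining > 0:
        p = pool_ab[idx]
        p = p / p.sum() if p.sum() > 0 else np.full(idx.size, 1.0 / idx.size)
        vec[idx] += rng.multinomial(remaining, p)
    return vec


def rc_bray(ca, cb, pool_freq, pool_ab, n_null: int = 999, seed=0) -> float:
    """Abundance-adjusted Raup-Crick index in [-1, 1].

    Null assemblies preserve each sample's richness and total abundance:
    species are drawn without replacement with probability proportional
    to their pool occurrence frequency, seeded with one individual each,
    and the remaining individuals are placed multinomially proportional
    to pool relative abundance. The index is the percentile of the
    observed Bray-Curtis distance in the null (ties counted half),
    rescaled to [-1, 1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ca = np.asarray(ca, dtype=float)
    cb = np.asarray(cb, dtype=float)
    pool_freq = np.asarray(pool_freq, dtype=float)
    pool_ab = np.asarray(pool_ab, dtype=float)
    n_pool = int((pool_freq > 0).sum())
    for label, c in (("a", ca), ("b", cb)):
        s = int((c > 0).sum())
        if s == 0:
            raise ValueError(f"community {label} is empty")
        if s > n_pool:
            raise ValueError(
                f"pool has {n_pool} species but community {label} has richness {s}"
            )
    obs = braycurtis(ca, cb)
    less = ties = 0
    for _ in range(n_null):
        xa = _null_assembly(ca.sum(), int((ca > 0).sum()), pool_freq, pool_ab, rng)
        xb = _null_assembly(cb.sum(), int((cb > 0).sum()), pool_freq, pool_ab, rng)
        bc = braycurtis(xa, xb)
        if np.isclose(bc, obs, rtol=0.0, atol=1e-12):
            ties += 1
        elif bc < obs:
            less += 1
    return float(2.0 * (less + 0.5 * ties) / n_null - 1.0)


def classify(bnti_value: float, rc: float | None) -> str:
    """Map (bNTI, RC_bray) to one of the five mechanism labels."""
    if bnti_value > 2.0:
        return "heterogeneous_selection"
    if bnti_value < -2.0:
        return "homogeneous_selection"
    if rc is None or (isinstance(rc, float) and np.isnan(rc)):
        raise ValueError("RC_bray required when |bNTI| <= 2")
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def within_group_pairs(metadata: pd.DataFrame, by=("ocean", "fraction", "depth_layer")):
    """All unordered sample pairs sharing the grouping key, with the key."""
    pairs = []
    for key, group in metadata.groupby(list(by), sort=True):
        for a, b in combinations(sorted(group.index), 2):
            pairs.append((a, b, key))
    return pairs


def pairwise_mechanisms(
    counts: pd.DataFrame,
    dmat: pd.DataFrame,
    pairs,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify every sample pair; returns one row per pair.

    ``counts`` must be an integer (e.g. rarefied) samples x taxa table;
    the regional pool (occurrence frequencies and relative abundances)
    derives from the full table. Per-pair RNG streams are derived from
    the seed and the pair's sample ids, so results do not depend on the
    order in which pairs are evaluated.
    """
    taxa = [t for t in counts.columns if t in dmat.index]
    if len(taxa) < 2:
        raise ValueError("counts and distance matrix share fewer than 2 taxa")
    x = counts[taxa].to_numpy(dtype=float)
    d = dmat.loc[taxa, taxa].to_numpy(dtype=float)
    sample_pos = {s: i for i, s in enumerate(counts.index)}
    pool_freq = (x > 0).mean(axis=0)
    pool_ab = x.sum(axis=0) / x.sum()

    rows = []
    for pair in pairs:
        a, b = pair[0], pair[1]
        extra = pair[2] if len(pair) > 2 else None
        rng = stage_rng(seed, "pair", *sorted((str(a), str(b))))
        ca, cb = x[sample_pos[a]], x[sample_pos[b]]
        try:
            z = bnti(ca, cb, d, n_null=n_null, seed=rng)
        except ValueError:
            # bMNTD invariant under tip shuffles (e.g. both communities span
            # the whole pool): no phylogenetic signal, defer to RC_bray
            z = 0.0
        rc = np.nan
        if abs(z) <= 2.0:
            rc = rc_bray(ca, cb, pool_freq, pool_ab, n_null=n_null, seed=rng)
        label = classify(z, None if np.isnan(rc) else rc)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "group": extra,
                "bmntd_obs": bmntd(ca, cb, d),
                "bnti": z,
                "rc_bray": rc,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def mechanism_fractions(
    calls: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    by=("ocean", "fraction", "depth_layer"),
    delta_t_binwidth: float | None = None,
) -> pd.DataFrame:
    """Label frequencies per group; fractions sum to 1 within each group.

    With ``delta_t_binwidth`` set, pairs are grouped by binned pairwise
    temperature difference instead (requires ``metadata`` with a
    ``temperature`` column).
    """
    calls = calls.copy()
    if delta_t_binwidth is not None:
        if metadata is None:
            raise ValueError("metadata required for deltaT grouping")
        t = metadata["temperature"]
        dt = (t.loc[calls["sample_a"]].to_numpy()
              - t.loc[calls["sample_b"]].to_numpy())
        calls["group"] = (np.abs(dt) // delta_t_binwidth) * delta_t_binwidth
    elif "group" not in calls or calls["group"].isna().all():
        key = metadata[list(by)]
        calls["group"] = [
            tuple(key.loc[a]) for a in calls["sample_a"]
        ]
    out = (
        calls.groupby("group")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for lab in LABELS:
        if lab not in out.columns:
            out[lab] = 0.0
    return out[list(LABELS)]
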