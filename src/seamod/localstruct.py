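"""Per-sample network structure and module abundance profiles.

Induced per-sample subnetworks of the global association network, local
modularity under the global partition, module relative-abundance
profiles, module counting, module-richness coupling, cross-dataset
module tracking and the two-phase module-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import stage_rng
from .netmodules import modularity

__all__ = [
    "sample_subnetwork",
    "local_modularity",
    "sample_modularity_table",
    "module_profiles",
    "modules_present",
    "richness_coupling",
    "track_modules",
    "phase_ratio_test",
]


def sample_subnetwork(global_network: nx.Graph, sample_asvs) -> nx.Graph:
    """Induced subgraph on the ASVs present in one sample."""
    present = set(sample_asvs) & set(global_network.nodes)
    return global_network.subgraph(present).copy()


def local_modularity(subgraph: nx.Graph, global_membership) -> float:
    """Modularity of a per-sample subgraph under the global partition.

    Raises on an edgeless subgraph (callers report those as missing).
    """
    if subgraph.number_of_edges() == 0:
        raise ValueError("local modularity undefined: subgraph has no edges")
    return modularity(subgraph, global_membership)


def sample_modularity_table(
    global_network: nx.Graph,
    counts: pd.DataFrame,
    membership,
) -> pd.DataFrame:
    """Per-sample table: nodes present, local Q, modules present, richness.

    ``local_q`` is NaN for samples whose induced subgraph has no edges.
    """
    rows = []
    for sample_id, row in counts.iterrows():
        present = row.index[row > 0]
        sub = sample_subnetwork(global_network, present)
        try:
            q = local_modularity(sub, membership)
        except ValueError:
            q = np.nan
        mods = {membership[n] for n in sub.nodes if n in membership}
        rows.append(
            {
                "sample_id": sample_id,
                "n_nodes_present": sub.number_of_nodes(),
                "local_q": q,
                "n_modules_present": len(mods),
                "richness": int((row > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def module_profiles(
    counts: pd.DataFrame,
    membership,
    denominator: str = "total",
) -> pd.DataFrame:
    """Per-sample module relative-abundance profile.

    With ``denominator="total"`` each module's fraction is its reads over
    all reads in the sample and the remainder is reported as
    ``unassigned`` (fractions + unassigned == 1). With ``"assigned"``
    fractions are over module-assigned reads only.
    """
    if denominator not in ("total", "assigned"):
        raise ValueError("denominator must be 'total' or 'assigned'")
    module_ids = sorted(set(membership.values()))
    asv_to_mod = {a: m for a, m in membership.items() if a in counts.columns}
    totals = counts.sum(axis=1).astype(float)
    out = pd.DataFrame(0.0, index=counts.index, columns=module_ids)
    for mod in module_ids:
        cols = [a for a, m in asv_to_mod.items() if m == mod]
        if cols:
            out[mod] = counts[cols].sum(axis=1).astype(float)
    assigned = out.sum(axis=1)
    if denominator == "total":
        denom = totals.replace(0.0, np.nan)
        out = out.div(denom, axis=0).fillna(0.0)
        out["unassigned"] = np.where(totals > 0, 1.0 - out[module_ids].sum(axis=1), 1.0)
    else:
        denom = assigned.replace(0.0, np.nan)
        out = out.div(denom, axis=0).fillna(0.0)
        out["unassigned"] = 0.0
    return out


def modules_present(profiles: pd.DataFrame, min_fraction: float = 0.01) -> pd.Series:
    """Number of modules above ``min_fraction`` of reads, per sample.

    With ``min_fraction=0`` counts every module with any read.
    """
    mods = [c for c in profiles.columns if c != "unassigned"]
    if min_fraction == 0:
        return (profiles[mods] > 0).sum(axis=1).rename("n_modules_present")
    return (profiles[mods] >= min_fraction).sum(axis=1).rename("n_modules_present")


def richness_coupling(n_modules: pd.Series, richness: pd.Series):
    """OLS of richness on the number of co-occurring modules.

    Returns ``(slope, r2, p)`` with a two-sided slope test.
    """
    x = np.asarray(n_modules, dtype=float)
    y = np.asarray(richness.loc[n_modules.index] if hasattr(richness, "loc") else richness,
                   dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for the regression")
    if np.allclose(x, x[0]):
        raise ValueError("number of modules present has zero variance")
    res = stats.linregress(x, y)
    return res.slope, res.rvalue**2, res.pvalue


def track_modules(external_counts: pd.DataFrame, membership, denominator: str = "total"):
    """Project module assignments onto an external table sharing the id scheme.

    Returns ``(profiles, coverage)`` where coverage is the assigned-read
    fraction per external sample. Zero id overlap yields all-unassigned
    profiles and a warning.
    """
    overlap = set(external_counts.columns) & set(membership)
    if not overlap:
        warnings.warn("no ASV id overlap with the module assignment; coverage is 0",
                      stacklevel=2)
    profiles = module_profiles(external_counts, membership, denominator="total")
    coverage = (1.0 - profiles["unassigned"]).rename("coverage")
    if denominator == "assigned":
        profiles = module_profiles(external_counts, membership, denominator="assigned")
    return profiles, coverage


@dataclass
class PhaseRatioResult:
    p_welch: float
    p_perm: float
    statistic: float
    log_ratios: pd.Series
    epsilon: float


def phase_ratio_test(
    profiles: pd.DataFrame,
    phase_labels: pd.Series,
    module_a=2,
    module_b=6,
    n_perm: int = 9999,
    seed: int = 0,
) -> PhaseRatioResult:
    """Two-sample test of the module a : module b abundance ratio between
    two phases.

    The statistic is Welch's t on ``log10((a + eps) / (b + eps))`` with
    ``eps`` one tenth of the smallest nonzero fraction of either module; a
    label-permutation p-value is reported alongside.
    """
    labels = phase_labels.loc[profiles.index]
    phases = sorted(labels.unique())
    if len(phases) != 2:
        raise ValueError(f"need exactly 2 phases, got {phases}")
    a = profiles[module_a].astype(float)
    b = profiles[module_b].astype(float)
    nz = pd.concat([a[a > 0], b[b > 0]])
    if nz.empty:
        raise ValueError("both modules are absent everywhere; ratio undefined")
    eps = float(nz.min()) / 10.0
    lr = np.log10((a + eps) / (b + eps))
    g0 = lr[labels == phases[0]]
    g1 = lr[labels == phases[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each phase needs at least 2 samples")
    t_obs, p_welch = stats.ttest_ind(g0, g1, equal_var=False)

    rng = stage_rng(seed, "phase_ratio")
    vals = lr.to_numpy()
    n0 = len(g0)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        t_b, _ = stats.ttest_ind(perm[:n0], perm[n0:], equal_var=False)
        if abs(t_b) >= abs(t_obs) - 1e-12:
            hits += 1
    p_perm = (hits + 1) / (n_perm + 1)
    return PhaseRatioResult(float(p_welch), float(p_perm), float(t_obs), lr, eps)
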