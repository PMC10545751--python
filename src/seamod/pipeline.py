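"""End-to-end orchestration: synthetic inputs through transport.

``run_all`` executes every stage from one :class:`~seamod.config.RunConfig`,
writes each stage's artifact as plain text under the run directory and
finishes with a manifest (parameter hash, seeds, file checksums) so a
re-run with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from . import io, localstruct, netmodules, preprocess, sparcc, synthdata, transport
from ._util import stage_rng
from .assembly import mechanism_fractions, pairwise_mechanisms, within_group_pairs
from .config import RunConfig

__all__ = ["RunResult", "run_all"]


@dataclass
class RunResult:
    """In-memory handles to every stage output of one run."""

    outdir: Path
    metadata: pd.DataFrame = None
    counts: pd.DataFrame = None
    tree_newick: str = None
    filtered: pd.DataFrame = None
    rarefied: pd.DataFrame = None
    diversity: pd.DataFrame = None
    edges: pd.DataFrame = None
    network: object = None
    assignment: object = None
    local_table: pd.DataFrame = None
    profiles: pd.DataFrame = None
    calls: pd.DataFrame = None
    fractions: pd.DataFrame = None
    trajectories: pd.DataFrame = None
    transport_matrix: object = None
    tracer_states: list = None
    station_tracer: pd.Series = None
    planted_membership: dict = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> RunResult:
    """Run every stage and write artifacts + manifest under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    res = RunResult(outdir=outdir)

    # --- synthetic inputs ------------------------------------------------
    specs = config.module_specs()
    meta = synthdata.generate_metadata(
        config.n_stations, config.depths, config.oceans, config.fractions,
        seed=seed, lat_range=config.lat_range,
    )
    tree_nwk = synthdata.generate_phylogeny(specs, seed=seed)
    counts, planted = synthdata.generate_counts(
        specs, meta, seed=seed, mean_depth=config.mean_seq_depth,
        asv_noise_sd=config.asv_noise_sd,
    )
    field_spec = config.velocity_field()
    traj = synthdata.generate_trajectories(
        field_spec, config.n_drifters, config.trajectory_days, seed=seed,
        lat_range=(config.grid_lat_bounds[0] + 2, config.grid_lat_bounds[1] - 2),
        lon_range=(config.grid_lon_bounds[0] + 2, config.grid_lon_bounds[1] - 2),
    )
    res.metadata, res.counts, res.tree_newick = meta, counts, tree_nwk
    res.trajectories, res.planted_membership = traj, planted
    io.write_metadata(meta, outdir / "metadata.csv")
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_newick(tree_nwk, outdir / "tree.nwk")
    io.write_trajectories(traj, outdir / "trajectories.csv")

    # --- preprocess ------------------------------------------------------
    per_ocean = {}
    for ocean in config.oceans:
        samples = meta.index[meta["ocean"] == ocean]
        per_ocean[ocean] = preprocess.abundance_filter(counts.loc[samples])
    kept = sorted(set().union(*(set(t.columns) for t in per_ocean.values())))
    filtered = counts[[c for c in counts.columns if c in kept]]
    rarefied = preprocess.rarefy(filtered, depth=config.rarefaction_depth, seed=seed)
    diversity = pd.concat(
        [preprocess.richness(rarefied), preprocess.ens_inverse_simpson(rarefied)], axis=1
    )
    res.filtered, res.rarefied, res.diversity = filtered, rarefied, diversity
    io.write_counts(filtered, outdir / "filtered.tsv")
    io.write_counts(rarefied, outdir / "rarefied.tsv")
    diversity.rename_axis("sample_id").to_csv(outdir / "diversity.tsv", sep="\t")

    # --- sparcc per subset ----------------------------------------------
    edge_frames = []
    for ocean in config.oceans:
        basin = per_ocean[ocean]
        for fraction in config.fractions:
            for layer in ("upper", "lower"):
                sel = meta.index[
                    (meta["ocean"] == ocean)
                    & (meta["fraction"] == fraction)
                    & (meta["depth_layer"] == layer)
                ]
                sub = basin.loc[basin.index.intersection(sel)]
                sub = sub.loc[:, sub.sum(axis=0) > 0]
                label = f"{ocean}|{fraction}|{layer}"
                if sub.shape[0] < 5 or sub.shape[1] < 4:
                    continue
                result = sparcc.sparcc_with_pvalues(
                    sub, n_boot=config.n_boot,
                    seed=int(stage_rng(seed, "sparcc", label).integers(2**31)),
                    subset_label=label,
                )
                edge_frames.append(
                    sparcc.significant_edges(result, r_min=config.r_min, alpha=config.alpha)
                )
    edges = pd.concat(edge_frames, ignore_index=True) if edge_frames else pd.DataFrame(
        columns=["asv_i", "asv_j", "r", "p_raw", "p_adj", "subset"]
    )
    res.edges = edges
    io.write_edges(edges, outdir / "edges.tsv")

    # --- global network + modules ---------------------------------------
    network = netmodules.merge_subset_networks(
        [g for _, g in edges.groupby("subset", sort=True)] or [edges]
    )
    assignment = netmodules.edge_betweenness_clusters(network)
    if network.number_of_edges() >= 2 and config.n_rewire > 0:
        p_null, _, _ = netmodules.rewire_null_test(
            network, n=config.n_rewire, p_rewire=config.p_rewire,
            seed=int(stage_rng(seed, "rewire").integers(2**31)),
        )
        assignment.null_p = p_null
    res.network, res.assignment = network, assignment
    io.write_membership(assignment.membership, outdir / "membership.tsv")
    (outdir / "network_stats.json").write_text(json.dumps({
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "modularity_q": assignment.modularity_q,
        "null_p": assignment.null_p,
        "n_modules": len(set(assignment.membership.values())),
    }, indent=2, sort_keys=True) + "\n")

    # --- local structure -------------------------------------------------
    local_table = localstruct.sample_modularity_table(
        network, rarefied, assignment.membership
    )
    profiles = localstruct.module_profiles(filtered, assignment.membership)
    res.local_table, res.profiles = local_table, profiles
    local_table.to_csv(outdir / "local_modularity.tsv", sep="\t")
    profiles.rename_axis("sample_id").to_csv(outdir / "module_profiles.tsv", sep="\t")

    # --- assembly mechanisms ---------------------------------------------
    tree = skbio.TreeNode.read(_io.StringIO(tree_nwk))
    dm = tree.tip_tip_distances()
    dmat = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    meta_r = meta.loc[rarefied.index]
    pairs = within_group_pairs(meta_r, by=("ocean", "fraction", "depth_layer"))
    if config.max_pairs_per_group is not None:
        rng = stage_rng(seed, "pair_subsample")
        by_group: dict = {}
        for p in pairs:
            by_group.setdefault(p[2], []).append(p)
        pairs = []
        for key in sorted(by_group):
            group = by_group[key]
            if len(group) > config.max_pairs_per_group:
                idx = sorted(rng.choice(len(group), config.max_pairs_per_group,
                                        replace=False))
                group = [group[i] for i in idx]
            pairs.extend(group)
    calls = pairwise_mechanisms(
        rarefied, dmat, pairs, n_null=config.n_null_assembly,
        seed=int(stage_rng(seed, "assembly").integers(2**31)),
    )
    fractions = mechanism_fractions(calls, meta_r)
    res.calls, res.fractions = calls, fractions
    calls.to_csv(outdir / "assembly_calls.tsv", sep="\t", index=False)
    fractions.to_csv(outdir / "mechanism_fractions.tsv", sep="\t")

    # --- transport --------------------------------------------------------
    grid = transport.GridSpec(
        dx=config.grid_dx, dy=config.grid_dy,
        lat_bounds=tuple(config.grid_lat_bounds),
        lon_bounds=tuple(config.grid_lon_bounds),
    )
    tm = transport.build_transport_matrix(traj, grid, dt_days=config.transport_dt_days)
    states = transport.advect(tm, n_years=config.n_years)
    stations = meta.reset_index().groupby("station", sort=True).agg(
        lat=("latitude", "first"), lon=("longitude", "first")
    )
    st_tracer = transport.station_tracer(tm, states[-1], stations)
    res.transport_matrix, res.tracer_states, res.station_tracer = tm, states, st_tracer
    io.write_transport_triplets(tm, outdir / "transport_matrix.tsv")
    yearly = pd.DataFrame(
        {f"year_{i}": s.concentration for i, s in enumerate(states)},
        index=pd.Index(tm.cells, name="cell"),
    )
    yearly.to_csv(outdir / "tracer_by_year.csv")
    st_tracer.rename_axis("station").to_csv(outdir / "station_tracer.tsv", sep="\t")

    # --- manifest ---------------------------------------------------------
    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    res.manifest = manifest
    return res
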