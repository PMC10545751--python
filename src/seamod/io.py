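"""Plain-text readers/writers for every stage artifact.

Count tables travel as TSV with ASVs as rows and samples as columns;
metadata and trajectories as CSV; trees as Newick; transition matrices
as sparse triplet TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_counts(counts: pd.DataFrame, path) -> None:
    """samples x ASVs frame -> TSV with ASV rows and sample columns."""
    counts.T.rename_axis("asv_id").to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T.astype(np.int64).rename_axis("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.strip() + "\n")


def read_newick(path) -> str:
    with open(path) as fh:
        return fh.read().strip()


def write_trajectories(traj: pd.DataFrame, path) -> None:
    out = traj.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    traj = pd.read_csv(path)
    traj["time"] = pd.to_datetime(traj["time"])
    return traj


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_membership(membership: dict, path) -> None:
    pd.Series(membership, name="module_id").rename_axis("asv_id").sort_index().to_csv(
        path, sep="\t"
    )


def read_membership(path) -> dict:
    s = pd.read_csv(path, sep="\t", index_col="asv_id")["module_id"]
    return s.to_dict()


def write_transport_triplets(tm, path) -> None:
    rows = []
    for i in range(tm.cells.size):
        for j in np.nonzero(tm.p[i])[0]:
            rows.append((int(tm.cells[i]), int(tm.cells[j]), tm.p[i, j]))
    pd.DataFrame(rows, columns=["cell_i", "cell_j", "p"]).to_csv(path, sep="\t", index=False)
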