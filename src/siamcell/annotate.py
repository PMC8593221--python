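"""Annotation in the learned embedding space.

A query cell is embedded and compared to every reference cell (20 per type
by default); the type with the smallest mean distance is assigned.  A
novelty filter flags queries whose best match does not stand out from the
remaining comparisons by at least ``z_threshold`` standard deviations —
those cells likely belong to a type absent from the reference.  KNN label
transfer and KNN-graph construction over the embedding are also provided,
and a reference set can be extended with a new cell type without retraining
the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .prep import ReferencePanel, ScaledMatrix
from .siamese import EmbeddingMatrix, TrainedModel, embed

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSet:
    """Embedded, labeled reference cells — the object annotation compares
    against.  Built once from a panel and cached in the model bundle so
    annotation needs only the model artifact."""

    embeddings: np.ndarray
    labels: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != self.embeddings.shape[0]:
            raise ValueError("one label per reference cell required")

    @property
    def types(self) -> list[str]:
        return sorted(set(self.labels))

    @classmethod
    def from_panel(
        cls,
        model: TrainedModel,
        x: ScaledMatrix,
        panel: ReferencePanel,
        partition: str = "train",
    ) -> "ReferenceSet":
        idx = panel.all_indices(partition)
        sub = ScaledMatrix(
            x.values[idx], [x.cell_ids[i] for i in idx], list(x.gene_ids)
        )
        emb = embed(model, sub)
        return cls(emb.values, panel.labels_of(partition), emb.cell_ids)


@dataclass
class DistanceTable:
    """Query x reference embedding distances, with reference type labels."""

    distances: np.ndarray  # (n_query, n_reference)
    query_ids: list[str]
    ref_labels: list[str]
    ref_ids: list[str]

    def type_means(self) -> pd.DataFrame:
        """Per-type arithmetic mean distance, one row per query cell."""
        df = pd.DataFrame(self.distances, index=self.query_ids)
        groups = pd.Series(self.ref_labels)
        means = df.T.groupby(groups.values).mean().T
        return means.reindex(sorted(means.columns), axis=1)


def reference_distances(
    model: TrainedModel, query: ScaledMatrix, ref: ReferenceSet
) -> DistanceTable:
    """Distances from every query cell to every reference cell, in the
    embedding space.  Row order matches the query."""
    if len(ref.labels) == 0:
        raise ValueError("reference set is empty")
    q = embed(model, query)
    diff = q.values[:, None, :] - ref.embeddings[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceTable(d, q.cell_ids, list(ref.labels), list(ref.cell_ids))


def assign_types(dt: DistanceTable) -> pd.DataFrame:
    """Assign each query cell the reference type with the closest average
    distance; exact ties are broken lexicographically by type name."""
    means = dt.type_means()  # columns already sorted lexicographically
    arr = means.to_numpy()
    best_col = arr.argmin(axis=1)  # argmin takes the first (lexicographic) tie
    ties = (arr == arr[np.arange(len(arr)), best_col][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d query cells had tied best types (lexicographic tie-break)", ties.sum())
    return pd.DataFrame(
        {
            "cell_id": dt.query_ids,
            "assigned_type": [means.columns[j] for j in best_col],
            "mean_distance": arr[np.arange(len(arr)), best_col],
        }
    )


def novelty_flags(
    dt: DistanceTable, z_threshold: float = 2.0, level: str = "type_mean"
) -> pd.DataFrame:
    """Flag query cells whose best match does not stand out.

    For each query take the comparison values c1..ck (per-type mean
    distances at ``level='type_mean'``, every reference-cell distance at
    ``level='cell'``); with c_min the smallest and R the remaining values,

        z = (mean(R) - c_min) / sd(R)

    and the cell is flagged novel iff z < z_threshold: a trustworthy match
    must sit at least ``z_threshold`` standard deviations below the rest.
    If sd(R) = 0 the z-score is +inf when mean(R) > c_min and 0 otherwise.
    """
    if level == "type_mean":
        comp = dt.type_means().to_numpy()
    elif level == "cell":
        comp = dt.distances
    else:
        raise ValueError(f"unknown level {level!r}")
    if comp.shape[1] < 3:
        raise ValueError("novelty needs at least 3 comparison values per cell")

    zs = np.empty(comp.shape[0])
    for i, row in enumerate(comp):
        j = int(row.argmin())
        rest = np.delete(row, j)
        sd = rest.std(ddof=1)
        if sd == 0.0:
            zs[i] = np.inf if rest.mean() > row[j] else 0.0
            logger.info("degenerate novelty comparison (sd=0) for %s", dt.query_ids[i])
        else:
            zs[i] = (rest.mean() - row[j]) / sd
    return pd.DataFrame(
        {
            "cell_id": dt.query_ids,
            "novelty_z": zs,
            "novel": zs < z_threshold,
        }
    )


def annotate_cells(
    model: TrainedModel,
    query: ScaledMatrix,
    ref: ReferenceSet,
    z_threshold: float = 2.0,
    novelty_level: str = "type_mean",
) -> pd.DataFrame:
    """Full annotation table: assigned type, mean distance, novelty z, flag."""
    dt = reference_distances(model, query, ref)
    out = assign_types(dt)
    nov = novelty_flags(dt, z_threshold=z_threshold, level=novelty_level)
    return out.merge(nov, on="cell_id")


def knn_annotate(
    ref: ReferenceSet, query_emb: EmbeddingMatrix, k: int = 3
) -> pd.DataFrame:
    """Transfer labels by majority vote among the k nearest reference cells.

    Vote ties are broken by the smallest mean neighbor distance, then
    lexicographically by type name.
    """
    n_ref = ref.embeddings.shape[0]
    if k > n_ref:
        raise ValueError(f"k={k} exceeds the {n_ref} reference cells")
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(ref.embeddings)
    dist, idx = nn.kneighbors(query_emb.values)
    labels = np.asarray(ref.labels, dtype=object)

    assigned, votes_col = [], []
    for drow, irow in zip(dist, idx):
        votes: dict[str, list[float]] = {}
        for d, i in zip(drow, irow):
            votes.setdefault(str(labels[i]), []).append(float(d))
        # (-count, mean distance, name): majority, then closest, then name
        ranked = sorted(
            votes.items(), key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0])
        )
        assigned.append(ranked[0][0])
        votes_col.append(";".join(f"{t}:{len(ds)}" for t, ds in sorted(votes.items())))
    return pd.DataFrame(
        {
            "cell_id": query_emb.cell_ids,
            "assigned_type": assigned,
            "votes": votes_col,
        }
    )


def knn_graph(
    emb: EmbeddingMatrix, labels: list[str], k: int, mutual: bool = False
) -> nx.Graph:
    """k-nearest-neighbor graph over embedded cells (undirected).

    With ``mutual=True`` an edge requires each endpoint to be among the
    other's k nearest.  Node attributes carry the cell label; the graph can
    be exported as an edge list for external force-directed layout.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = emb.values.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(emb.values)
    _, idx = nn.kneighbors(emb.values)
    g = nx.Graph()
    for i, cell in enumerate(emb.cell_ids):
        g.add_node(cell, label=labels[i])
    neighbor_sets = [set(row[1:]) for row in idx]  # row[0] is the cell itself
    for i in range(n):
        for j in neighbor_sets[i]:
            if mutual and i not in neighbor_sets[j]:
                continue
            g.add_edge(emb.cell_ids[i], emb.cell_ids[int(j)])
    return g


def write_graph(g: nx.Graph, path) -> None:
    """Edge-list TSV export (node_a, node_b) with a node-label sidecar."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in g.edges:
            fh.write(f"{a}\t{b}\n")


def update_reference(
    ref: ReferenceSet,
    model: TrainedModel,
    new_cells: ScaledMatrix,
    label: str,
    n_ref: int = 20,
    seed: int = 0,
    merge: bool = False,
) -> ReferenceSet:
    """Add a new cell type to the reference set without retraining.

    Samples up to ``n_ref`` of the new cells, embeds them with the frozen
    model, and returns an extended reference set.  Network weights are
    untouched.  Adding a label that already exists is an error unless
    ``merge=True``.
    """
    if label in ref.labels and not merge:
        raise ValueError(f"type {label!r} already in the reference (pass merge=True to extend)")
    rng = np.random.default_rng(seed)
    n = new_cells.values.shape[0]
    take = rng.choice(n, size=min(n_ref, n), replace=False) if n > n_ref else np.arange(n)
    sub = ScaledMatrix(
        new_cells.values[np.sort(take)],
        [new_cells.cell_ids[i] for i in np.sort(take)],
        list(new_cells.gene_ids),
    )
    emb = embed(model, sub)
    return ReferenceSet(
        embeddings=np.vstack([ref.embeddings, emb.values]),
        labels=list(ref.labels) + [label] * emb.values.shape[0],
        cell_ids=list(ref.cell_ids) + emb.cell_ids,
    )
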