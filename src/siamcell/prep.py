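"""Input preparation: per-cell max scaling, reference-panel sampling, and
construction of the labeled pair corpus for contrastive training.

The normalization is deliberately minimal — each cell's counts are divided
by that cell's maximum count, so every input value lies in [0, 1] and the
transform is invariant to library size.  No log transform and no
library-size normalization are applied; platform/batch robustness rests on
this per-cell scaling plus the learned metric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .sc_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScaledMatrix:
    """Counts scaled per cell into [0, 1]; rows with any signal peak at 1."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    n_zero_cells: int = 0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def max_scale(m: CountMatrix) -> ScaledMatrix:
    """Divide each cell's counts by that cell's maximum count.

    All-zero cells are left as zeros and reported with a warning — they carry
    no expression signal but are not an error.
    """
    maxima = m.values.max(axis=1)
    zero = maxima == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.warning("%d all-zero cells left unscaled", n_zero)
    denom = np.where(zero, 1.0, maxima)
    return ScaledMatrix(
        m.values / denom[:, None],
        list(m.cell_ids),
        list(m.gene_ids),
        n_zero_cells=n_zero,
    )


@dataclass
class ReferencePanel:
    """Per-type sampled reference cells split into disjoint train/validation
    partitions, plus the frozen gene space they live in.

    Indices refer to rows of the matrix the panel was sampled from.
    """

    types: tuple[str, ...]
    train_idx: dict[str, np.ndarray]
    val_idx: dict[str, np.ndarray]
    gene_space: tuple[str, ...]
    cell_ids: list[str]
    seed: int
    excluded: dict[str, int] = field(default_factory=dict)

    def indices(self, partition: str) -> dict[str, np.ndarray]:
        if partition == "train":
            return self.train_idx
        if partition == "val":
            return self.val_idx
        raise ValueError(f"unknown partition {partition!r}")

    def all_indices(self, partition: str) -> np.ndarray:
        return np.concatenate([self.indices(partition)[t] for t in self.types])

    def labels_of(self, partition: str) -> list[str]:
        return [t for t in self.types for _ in self.indices(partition)[t]]


def sample_reference(
    m: CountMatrix,
    labels: dict[str, str],
    n_per_type: int = 30,
    n_train: int = 20,
    n_val: int = 10,
    min_cells: int = 30,
    seed: int = 0,
) -> ReferencePanel:
    """Randomly select ``n_per_type`` cells per type and split them into
    train/validation partitions.

    Types with fewer than ``min_cells`` cells are excluded and reported.
    Sampling is without replacement and fully reproducible from *seed*.
    """
    if n_train + n_val != n_per_type:
        raise ValueError("n_train + n_val must equal n_per_type")
    if min_cells < n_per_type:
        raise ValueError("min_cells must be >= n_per_type")
    by_type: dict[str, list[int]] = {}
    n_unlabeled = 0
    for i, cell in enumerate(m.cell_ids):
        typ = labels.get(cell)
        if typ is None:
            n_unlabeled += 1
            continue
        by_type.setdefault(typ, []).append(i)
    if n_unlabeled:
        logger.warning("%d cells have no label and were ignored", n_unlabeled)

    rng = np.random.default_rng(seed)
    train_idx: dict[str, np.ndarray] = {}
    val_idx: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for typ in sorted(by_type):
        idx = np.asarray(by_type[typ])
        if len(idx) < min_cells:
            excluded[typ] = len(idx)
            continue
        pick = rng.choice(idx, size=n_per_type, replace=False)
        train_idx[typ] = np.sort(pick[:n_train])
        val_idx[typ] = np.sort(pick[n_train:])
    if excluded:
        logger.info("excluded types with < %d cells: %s", min_cells, excluded)
    if not train_idx:
        raise ValueError(f"no cell type has at least {min_cells} cells")
    return ReferencePanel(
        types=tuple(sorted(train_idx)),
        train_idx=train_idx,
        val_idx=val_idx,
        gene_space=tuple(m.gene_ids),
        cell_ids=list(m.cell_ids),
        seed=seed,
        excluded=excluded,
    )


@dataclass
class PairSet:
    """Indexed cell pairs with binary similarity labels (1 = same type)."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    labels: np.ndarray
    scheme: str
    seed: int

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, cell_ids: list[str], path) -> None:
        """Export as (cell_a, cell_b, label) for audit."""
        with open(path, "w") as fh:
            fh.write("cell_a\tcell_b\tlabel\n")
            for a, b, y in zip(self.idx_a, self.idx_b, self.labels):
                fh.write(f"{cell_ids[a]}\t{cell_ids[b]}\t{int(y)}\n")


def make_pairs(
    panel: ReferencePanel,
    partition: str = "train",
    neg_ratio: float = 1.0,
    scheme: str = "all_pos_sampled_neg",
    seed: int = 0,
) -> PairSet:
    """Build the labeled pair corpus from one panel partition.

    ``all_pos_sampled_neg``: every within-type unordered pair (C(n,2) per
    type) labeled 1, plus ``round(neg_ratio * n_positive)`` between-type
    pairs sampled uniformly without replacement, labeled 0.  ``exhaustive``:
    every unordered pair of partition cells, labeled by type identity.
    The final pair order is shuffled reproducibly from *seed*.
    """
    if scheme not in ("all_pos_sampled_neg", "exhaustive"):
        raise ValueError(f"unknown scheme {scheme!r}")
    idx = panel.indices(partition)
    types = panel.types
    rng = np.random.default_rng(seed)

    pos = [
        (a, b)
        for t in types
        for a, b in itertools.combinations(sorted(idx[t]), 2)
    ]
    neg_all = [
        (min(a, b), max(a, b))
        for t1, t2 in itertools.combinations(types, 2)
        for a in idx[t1]
        for b in idx[t2]
    ]

    if scheme == "exhaustive":
        pairs = [(a, b, 1) for a, b in pos] + [(a, b, 0) for a, b in neg_all]
    else:
        n_neg = int(round(neg_ratio * len(pos)))
        if n_neg > 0 and len(types) < 2:
            raise ValueError("cannot sample negative pairs from a single-type panel")
        if n_neg > len(neg_all):
            raise ValueError(
                f"requested {n_neg} negative pairs but only {len(neg_all)} "
                "distinct between-type pairs exist"
            )
        chosen = rng.choice(len(neg_all), size=n_neg, replace=False)
        pairs = [(a, b, 1) for a, b in pos] + [neg_all[i] + (0,) for i in sorted(chosen)]

    order = rng.permutation(len(pairs))
    arr = np.asarray(pairs, dtype=np.int64)[order]
    return PairSet(
        idx_a=arr[:, 0].copy(),
        idx_b=arr[:, 1].copy(),
        labels=arr[:, 2].astype(np.int8),
        scheme=scheme,
        seed=seed,
    )
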