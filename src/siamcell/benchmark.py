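"""Metric comparison: learned embedding distance vs Euclidean/cosine on
top-variable genes, summarized by a signal-to-noise statistic.

For each query type, 20 cells are compared pairwise against 20 cells of
every reference type.  With mu1/sigma1 the mean and standard deviation of
the distances to the best-matching (smallest-mean) type and mu2/sigma2
those of the second best,

    SNR = |mu1 - mu2| / |sigma1 + sigma2|

a high SNR means the best match stands clearly apart from the runner-up.
Baseline metrics use the top-n most variable genes; the learned metric uses
all genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import ScaledMatrix, max_scale
from .sc_io import CountMatrix
from .siamese import TrainedModel, embed

logger = logging.getLogger(__name__)


def top_variable_genes(m: CountMatrix, n: int, on: str = "max_scaled") -> list[str]:
    """Genes ranked by expression variance, descending; ties by name.

    Variance is computed on max-scaled values by default (``on='raw'``
    ranks on raw counts instead).
    """
    if n > m.n_genes:
        raise ValueError(f"requested {n} genes but the matrix has {m.n_genes}")
    values = max_scale(m).values if on == "max_scaled" else m.values
    var = values.var(axis=0)
    order = sorted(range(m.n_genes), key=lambda j: (-var[j], m.gene_ids[j]))
    return [m.gene_ids[j] for j in order[:n]]


def baseline_distance(
    x: ScaledMatrix,
    pairs: tuple[np.ndarray, np.ndarray],
    metric: str = "euclidean",
    genes: list[str] | None = None,
) -> np.ndarray:
    """Per-pair Euclidean or cosine distance on a restricted gene set.

    Cosine distance is 1 - cosine similarity; a pair involving a zero
    vector on the restricted genes gets distance 1 (logged).
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    values = x.values
    if genes is not None:
        pos = {g: j for j, g in enumerate(x.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:5]} ...")
        values = values[:, [pos[g] for g in genes]]
    a, b = values[np.asarray(pairs[0])], values[np.asarray(pairs[1])]
    if metric == "euclidean":
        return np.sqrt(((a - b) ** 2).sum(axis=1))
    na = np.sqrt((a**2).sum(axis=1))
    nb = np.sqrt((b**2).sum(axis=1))
    zero = (na == 0) | (nb == 0)
    if zero.any():
        logger.warning("%d cosine pairs involve a zero vector; distance set to 1", zero.sum())
    denom = np.where(zero, 1.0, na * nb)
    sim = np.where(zero, 0.0, (a * b).sum(axis=1) / denom)
    return 1.0 - sim


def _snn_pair_distance(model: TrainedModel, x: ScaledMatrix):
    emb = embed(model, x).values

    def fn(pairs):
        a, b = emb[np.asarray(pairs[0])], emb[np.asarray(pairs[1])]
        return np.sqrt(((a - b) ** 2).sum(axis=1))

    return fn


def pairwise_type_distances(
    x: ScaledMatrix,
    labels: dict[str, str],
    metric_fn,
    n_cells: int = 20,
    seed: int = 0,
    mode: str = "grid",
) -> dict[tuple[str, str], np.ndarray]:
    """Sample ``n_cells`` cells per type and collect distance samples for
    every ordered (query type, reference type) pair.

    ``grid`` pairs every sampled query cell with every sampled reference
    cell (self type-pairs exclude identical-cell pairings); ``paired``
    draws one reference partner per query cell.  Types with fewer than
    ``n_cells`` cells are excluded and logged.  Reproducible from *seed*.
    """
    if mode not in ("grid", "paired"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[int]] = {}
    for i, cell in enumerate(x.cell_ids):
        t = labels.get(cell)
        if t is not None:
            by_type.setdefault(t, []).append(i)
    sampled: dict[str, np.ndarray] = {}
    for t in sorted(by_type):
        idx = np.asarray(by_type[t])
        if len(idx) < n_cells:
            logger.info("type %s has %d < %d cells; excluded", t, len(idx), n_cells)
            continue
        sampled[t] = np.sort(rng.choice(idx, size=n_cells, replace=False))
    if len(sampled) < 2:
        raise ValueError("need at least two types with enough cells")

    out: dict[tuple[str, str], np.ndarray] = {}
    for tq in sampled:
        for tr in sampled:
            qi, ri = sampled[tq], sampled[tr]
            if mode == "grid":
                A, B = np.meshgrid(qi, ri, indexing="ij")
                a, b = A.ravel(), B.ravel()
                if tq == tr:
                    keep = a != b
                    a, b = a[keep], b[keep]
            else:
                partners = rng.permutation(ri)
                if tq == tr:  # avoid identical-cell pairings in self pairs
                    while np.any(partners == qi):
                        partners = rng.permutation(ri)
                a, b = qi, partners
            out[(tq, tr)] = metric_fn((a, b))
    return out


@dataclass
class SNRResult:
    """Best/second-best match separation for one query type."""

    query_type: str
    best_type: str
    second_type: str
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    snr: float
    metric: str = ""
    gene_set: int | str = "all"

    @property
    def correct(self) -> bool:
        return self.best_type == self.query_type


def snr(samples: dict[str, np.ndarray], query_type: str = "") -> SNRResult:
    """SNR between the two closest reference types by mean distance."""
    if len(samples) < 2:
        raise ValueError("SNR needs at least two reference types")
    stats = sorted(
        ((float(np.mean(v)), float(np.std(v)), t) for t, v in samples.items()),
        key=lambda s: (s[0], s[2]),
    )
    (mu1, s1, t1), (mu2, s2, t2) = stats[0], stats[1]
    denom = abs(s1 + s2)
    if denom == 0.0:
        value = np.inf if mu1 != mu2 else 0.0
        logger.info("degenerate SNR (sigma1+sigma2=0) for %s", query_type)
    else:
        value = abs(mu1 - mu2) / denom
    return SNRResult(query_type, t1, t2, mu1, s1, mu2, s2, float(value))


def compare_metrics(
    m: CountMatrix,
    labels: dict[str, str],
    model: TrainedModel,
    gene_counts: list[int] = (1000, 10000),
    n_cells: int = 20,
    seed: int = 0,
    mode: str = "grid",
) -> pd.DataFrame:
    """Full metric comparison report.

    Euclidean and cosine run on each top-variable gene set; the learned
    metric runs on all genes.  One row per (metric, gene set, query type)
    with the SNR decomposition and a correctness flag (best match equals
    the true type).  The same seed drives cell sampling for every metric so
    the comparison is paired.
    """
    x = max_scale(m)
    rows = []

    def add(metric_name: str, gene_set, metric_fn):
        samples = pairwise_type_distances(
            x, labels, metric_fn, n_cells=n_cells, seed=seed, mode=mode
        )
        types = sorted({t for t, _ in samples})
        for tq in types:
            res = snr({tr: samples[(tq, tr)] for tr in types}, query_type=tq)
            res.metric, res.gene_set = metric_name, gene_set
            rows.append(res)

    for n in gene_counts:
        genes = top_variable_genes(m, n)
        for metric in ("euclidean", "cosine"):
            add(metric, n, lambda pairs, mt=metric, g=genes: baseline_distance(x, pairs, mt, g))
    add("snn", "all", _snn_pair_distance(model, x))

    return pd.DataFrame(
        {
            "metric": [r.metric for r in rows],
            "gene_set": [r.gene_set for r in rows],
            "query_type": [r.query_type for r in rows],
            "best_type": [r.best_type for r in rows],
            "second_type": [r.second_type for r in rows],
            "mu1": [r.mu1 for r in rows],
            "sigma1": [r.sigma1 for r in rows],
            "mu2": [r.mu2 for r in rows],
            "sigma2": [r.sigma2 for r in rows],
            "snr": [r.snr for r in rows],
            "correct": [r.correct for r in rows],
        }
    )
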