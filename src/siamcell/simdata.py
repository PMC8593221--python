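"""Synthetic scRNA-seq count data with known cell-type structure.

The generator draws counts from a gamma-Poisson (negative binomial) model,
the standard overdispersed description of UMI counts.  Each gene g has a
baseline mean b_g (gamma-distributed across genes, so expression levels are
heterogeneous); each cell type elevates a disjoint block of marker genes by
a multiplicative effect; each cell scales its whole profile by a log-normal
library-size factor.  The per-type generative means, marker assignments and
library parameters are recorded in a truth record so tests can assert
against the ground truth.

Scenario builders reshape this core into the situations a reference-mapping
tool must handle: a platform shift (same biology, different depth and
noise), a novel cell type absent from training, a type hiding subtype
structure, a cross-species query reachable only through an ortholog map,
and a cell-state contrast where two populations share markers and differ by
a correlated multiplicative program (nearly identical mean direction, hence
hard for cosine or Euclidean distance on raw profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .sc_io import CountMatrix, OrthologMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TypeSpec:
    """One cell type: marker block size and multiplicative marker effect."""

    name: str
    n_cells: int = 60
    n_markers: int = 10
    marker_effect: float = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults describe a compact six-type immune-like dataset: 300 genes,
    60 cells per type, 10 disjoint marker genes per type elevated 4x, a
    mean baseline of 1 count per gene, negative-binomial dispersion
    (gamma shape) 2.0, and a 0.35-sigma log-normal library-size spread.
    """

    n_genes: int = 300
    types: tuple[TypeSpec, ...] = (
        TypeSpec("B"),
        TypeSpec("DC"),
        TypeSpec("Mono"),
        TypeSpec("NK"),
        TypeSpec("RBC"),
        TypeSpec("T"),
    )
    baseline: float = 1.0
    dispersion: float | None = 2.0  # NB size; None = Poisson limit
    libsize_sigma: float = 0.35
    marker_overlap: int = 0  # markers shared between consecutive types
    seed: int = 0

    def __post_init__(self) -> None:
        names = [t.name for t in self.types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate type names")
        demand = sum(t.n_markers for t in self.types) - self.marker_overlap * max(
            0, len(self.types) - 1
        )
        if demand > self.n_genes:
            raise ValueError(
                f"marker demand ({demand}) exceeds n_genes ({self.n_genes})"
            )


@dataclass
class Truth:
    """Ground truth behind a simulated matrix."""

    gene_means: np.ndarray  # (n_types, n_genes) pre-library-size means
    markers: dict[str, list[str]]
    type_order: list[str]
    config: SimConfig
    extras: dict = field(default_factory=dict)


def _build_structure(cfg: SimConfig) -> Truth:
    """Baseline means and marker assignment — shared across scenario arms."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    # gamma(2, baseline/2): mean=baseline, CV ~ 0.7 across genes
    base = rng.gamma(shape=2.0, scale=cfg.baseline / 2.0, size=cfg.n_genes)
    base = np.maximum(base, 0.05)  # keep every gene expressible
    gene_ids = [f"g{j}" for j in range(cfg.n_genes)]

    means = np.tile(base, (len(cfg.types), 1))
    markers: dict[str, list[str]] = {}
    cursor = 0
    for k, t in enumerate(cfg.types):
        start = cursor
        block = list(range(start, start + t.n_markers))
        cursor = start + t.n_markers - cfg.marker_overlap
        means[k, block] *= t.marker_effect
        markers[t.name] = [gene_ids[j] for j in block]
    return Truth(
        gene_means=means,
        markers=markers,
        type_order=[t.name for t in cfg.types],
        config=cfg,
    )


def _draw_counts(
    truth: Truth,
    cfg: SimConfig,
    rng: np.random.Generator,
    cell_prefix: str = "c",
    means_override: np.ndarray | None = None,
    libsize_sigma: float | None = None,
    dispersion: float | None | str = "cfg",
) -> tuple[CountMatrix, dict[str, str]]:
    means = truth.gene_means if means_override is None else means_override
    sigma = cfg.libsize_sigma if libsize_sigma is None else libsize_sigma
    disp = cfg.dispersion if dispersion == "cfg" else dispersion

    rows, cell_ids, labels = [], [], {}
    counter = 0
    for k, t in enumerate(cfg.types):
        lib = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=t.n_cells)
        mu = lib[:, None] * means[k][None, :]
        if disp is None:
            block = rng.poisson(mu)
        else:
            p = disp / (disp + mu)
            block = rng.negative_binomial(disp, p)
        rows.append(block)
        for _ in range(t.n_cells):
            cid = f"{cell_prefix}{counter}"
            cell_ids.append(cid)
            labels[cid] = t.name
            counter += 1
    values = np.vstack(rows).astype(np.float64)
    gene_ids = [f"g{j}" for j in range(cfg.n_genes)]
    return CountMatrix(values, cell_ids, gene_ids), labels


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, dict[str, str], Truth]:
    """Draw one cells x genes count matrix plus labels and the truth record.

    Fully reproducible from ``cfg.seed``.
    """
    truth = _build_structure(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    m, labels = _draw_counts(truth, cfg, rng)
    return m, labels, truth


@dataclass
class ScenarioBundle:
    """Self-describing train/query split with expected outcomes attached."""

    name: str
    train: CountMatrix
    train_labels: dict[str, str]
    query: CountMatrix
    query_labels: dict[str, str]
    truth: Truth
    ortholog_map: OrthologMap | None = None
    expected: dict = field(default_factory=dict)


_SCENARIOS = ("platform_shift", "novel_type", "subtype_split", "cross_species", "state_shift")


def make_scenario(name: str, cfg: SimConfig | None = None, **kwargs) -> ScenarioBundle:
    """Build a named scenario bundle; see the module docstring for the list."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {_SCENARIOS}")
    cfg = cfg or SimConfig()
    fn = globals()[f"_scenario_{name}"]
    return fn(cfg, **kwargs)


def _scenario_platform_shift(
    cfg: SimConfig, query_libsize_sigma: float = 0.7, query_dispersion: float | None = 1.0
) -> ScenarioBundle:
    truth = _build_structure(cfg)
    rng_train = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    rng_query = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    train, train_labels = _draw_counts(truth, cfg, rng_train)
    query, query_labels = _draw_counts(
        truth, cfg, rng_query, cell_prefix="q",
        libsize_sigma=query_libsize_sigma, dispersion=query_dispersion,
    )
    return ScenarioBundle(
        "platform_shift", train, train_labels, query, query_labels, truth,
        expected={"query_libsize_sigma": query_libsize_sigma,
                  "query_dispersion": query_dispersion},
    )


def _scenario_novel_type(
    cfg: SimConfig, novel_holdout: tuple[str, ...] = ("Endo",), n_query_per_type: int = 30
) -> ScenarioBundle:
    """Training matrix lacks the held-out type(s); the query has every type."""
    known = [t.name for t in cfg.types if t.name not in novel_holdout]
    if len(known) == len(cfg.types):
        # extend the config with a fresh holdout type carrying its own markers
        extra = tuple(TypeSpec(nm) for nm in novel_holdout)
        cfg = replace(cfg, types=cfg.types + extra)
    truth = _build_structure(cfg)
    train_cfg = replace(
        cfg, types=tuple(t for t in cfg.types if t.name not in novel_holdout)
    )
    train_truth = Truth(
        gene_means=np.vstack(
            [truth.gene_means[truth.type_order.index(t.name)] for t in train_cfg.types]
        ),
        markers={t.name: truth.markers[t.name] for t in train_cfg.types},
        type_order=[t.name for t in train_cfg.types],
        config=train_cfg,
    )
    rng_train = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    rng_query = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    train, train_labels = _draw_counts(train_truth, train_cfg, rng_train)
    query_cfg = replace(
        cfg, types=tuple(replace(t, n_cells=n_query_per_type) for t in cfg.types)
    )
    query, query_labels = _draw_counts(truth, query_cfg, rng_query, cell_prefix="q")
    return ScenarioBundle(
        "novel_type", train, train_labels, query, query_labels, truth,
        expected={"novel_types": list(novel_holdout)},
    )


def _scenario_subtype_split(
    cfg: SimConfig, parent: str | None = None, n_sub_markers: int = 6, sub_effect: float = 4.0
) -> ScenarioBundle:
    """One training type is secretly a mixture of two subtypes that differ
    by an extra marker block; labels exist at both granularities."""
    parent = parent or cfg.types[0].name
    names = [t.name for t in cfg.types]
    if parent not in names:
        raise ValueError(f"parent type {parent!r} not in config")
    k = names.index(parent)
    pt = cfg.types[k]
    half = pt.n_cells // 2
    sub_a = replace(pt, name=f"{parent}.sub1", n_cells=half)
    sub_b = replace(pt, name=f"{parent}.sub2", n_cells=pt.n_cells - half)
    sub_cfg = replace(
        cfg, types=cfg.types[:k] + (sub_a, sub_b) + cfg.types[k + 1 :]
    )
    truth = _build_structure(sub_cfg)
    # give sub2 its own extra program on top of the shared parent markers
    j2 = truth.type_order.index(sub_b.name)
    shared = truth.markers[sub_a.name]
    own_markers = truth.markers[sub_b.name][:n_sub_markers]
    truth.markers[sub_b.name] = shared + own_markers
    base_row = truth.gene_means[truth.type_order.index(sub_a.name)].copy()
    own = [int(g[1:]) for g in own_markers]  # gene ids are "g<index>"
    base_row[own] *= sub_effect
    truth.gene_means[j2] = base_row
    rng_train = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    rng_query = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    train, sub_labels = _draw_counts(truth, sub_cfg, rng_train)
    query, query_sub_labels = _draw_counts(truth, sub_cfg, rng_query, cell_prefix="q")

    def coarsen(lbls):
        return {c: (parent if t.startswith(parent + ".") else t) for c, t in lbls.items()}

    return ScenarioBundle(
        "subtype_split", train, coarsen(sub_labels), query, coarsen(query_sub_labels),
        truth,
        expected={
            "parent": parent,
            "train_sub_labels": sub_labels,
            "query_sub_labels": query_sub_labels,
        },
    )


def _scenario_cross_species(
    cfg: SimConfig, unmappable_fraction: float = 0.2, prefix: str = "mm_"
) -> ScenarioBundle:
    """Query genes live in a foreign namespace reachable via an ortholog map;
    a fraction of genes has no ortholog.

    Unmappable genes are the lowest-expressed non-marker genes: curated
    ortholog tables cover strong, well-studied genes best, and this choice
    guarantees that the mapped genes retain at least (1 - unmappable
    fraction) of every cell's total counts.
    """
    truth = _build_structure(cfg)
    rng_train = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    rng_query = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    train, train_labels = _draw_counts(truth, cfg, rng_train)
    query, query_labels = _draw_counts(truth, cfg, rng_query, cell_prefix="q")

    marker_genes = {g for gs in truth.markers.values() for g in gs}
    background = [g for g in query.gene_ids if g not in marker_genes]
    n_unmappable = int(round(unmappable_fraction * cfg.n_genes))
    if n_unmappable > len(background):
        raise ValueError("unmappable fraction exceeds the non-marker background")
    baseline = dict(zip(query.gene_ids, truth.gene_means.min(axis=0)))
    unmappable = set(sorted(background, key=lambda g: (baseline[g], g))[:n_unmappable])

    renamed = [prefix + g for g in query.gene_ids]
    query_foreign = CountMatrix(query.values, query.cell_ids, renamed)
    mapping = {prefix + g: g for g in query.gene_ids if g not in unmappable}
    om = OrthologMap(mapping, n_input_rows=len(mapping))
    return ScenarioBundle(
        "cross_species", train, train_labels, query_foreign, query_labels, truth,
        ortholog_map=om,
        expected={"unmappable_fraction": unmappable_fraction,
                  "unmappable_genes": sorted(unmappable)},
    )


def _scenario_state_shift(
    cfg: SimConfig,
    base_type: str | None = None,
    program_fraction: float = 0.3,
    program_effect: float = 1.6,
) -> ScenarioBundle:
    """Two cell states share the same marker block and differ only by a
    correlated multiplicative program over a random gene subset, so their
    generative mean profiles are nearly parallel (cosine similarity of the
    means is stored in the bundle; > 0.95 at the defaults)."""
    base_type = base_type or cfg.types[0].name
    names = [t.name for t in cfg.types]
    if base_type not in names:
        raise ValueError(f"base type {base_type!r} not in config")
    k = names.index(base_type)
    bt = cfg.types[k]
    st_a = replace(bt, name=f"{base_type}.state1")
    st_b = replace(bt, name=f"{base_type}.state2", n_markers=0)
    state_cfg = replace(cfg, types=cfg.types[:k] + (st_a, st_b) + cfg.types[k + 1 :])
    truth = _build_structure(state_cfg)
    ja = truth.type_order.index(st_a.name)
    jb = truth.type_order.index(st_b.name)
    # state2 = state1 elevated by a correlated program on a random gene subset
    rng_prog = np.random.default_rng(np.random.SeedSequence([cfg.seed, 505]))
    n_prog = int(round(program_fraction * cfg.n_genes))
    program = rng_prog.choice(cfg.n_genes, size=n_prog, replace=False)
    row = truth.gene_means[ja].copy()
    row[program] *= program_effect
    truth.gene_means[jb] = row
    truth.markers[st_b.name] = list(truth.markers[st_a.name])
    cos = float(
        truth.gene_means[ja] @ truth.gene_means[jb]
        / (np.linalg.norm(truth.gene_means[ja]) * np.linalg.norm(truth.gene_means[jb]))
    )
    rng_train = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    rng_query = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303]))
    train, train_labels = _draw_counts(truth, state_cfg, rng_train)
    query, query_labels = _draw_counts(truth, state_cfg, rng_query, cell_prefix="q")
    return ScenarioBundle(
        "state_shift", train, train_labels, query, query_labels, truth,
        expected={
            "state_types": [st_a.name, st_b.name],
            "mean_cosine_similarity": cos,
            "program_genes": [f"g{j}" for j in sorted(program)],
        },
    )
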