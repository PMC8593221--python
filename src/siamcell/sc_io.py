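"""Reading and writing count matrices, labels, ortholog maps and model bundles.

Count matrices come in as 10x-style Matrix Market triplet directories
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``/``genes.tsv``) or as
dense CSV/TSV with a header row of gene identifiers and a first column of
cell identifiers.  Everything downstream works on the in-memory
:class:`CountMatrix`.

The module also owns alignment of an arbitrary query matrix onto the frozen
gene space of a trained model — including cross-species projection through
an ortholog map, where target genes without a mapped source gene are
zero-filled — and the serialization of a complete annotation asset
(:class:`ModelBundle`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = "1"


class BundleVersionError(RuntimeError):
    """Raised when a serialized model bundle has an incompatible format tag."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())[:5]
        raise ValueError(f"duplicate {what}: {dupes} ...")


def _dedupe(ids: list[str], what: str) -> list[str]:
    """Disambiguate duplicate identifiers by suffixing ``.1``, ``.2``, ..."""
    seen: dict[str, int] = {}
    out = []
    n_dupes = 0
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
            n_dupes += 1
        else:
            seen[g] = 0
            out.append(g)
    if n_dupes:
        logger.warning("disambiguated %d duplicate %s by suffixing", n_dupes, what)
    return out


@dataclass
class CountMatrix:
    """Raw counts, cells x genes, with stable cell and gene identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes array")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if np.any(self.values < 0):
            raise ValueError("negative entries are not valid counts")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class OrthologMap:
    """Resolved one-to-at-most-one mapping from source to target gene ids."""

    mapping: Mapping[str, str]
    n_input_rows: int = 0
    n_dropped_ambiguous: int = 0

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class ModelBundle:
    """Self-contained annotation asset: trained weights + frozen gene space
    + reference embeddings, so annotation needs no original training data."""

    model: "object"  # siamese.TrainedModel
    reference: "object"  # annotate.ReferenceSet
    version: str = BUNDLE_FORMAT_VERSION
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_column(path: Path, prefer_second: bool = False) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    col = 1 if (prefer_second and df.shape[1] > 1) else 0
    return df[col].tolist()


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from an MTX triplet directory or a dense CSV/TSV.

    The on-disk MTX is taken to be genes x cells (10x convention) and is
    transposed on read.  Dense files are cells x genes with gene ids in the
    header and cell ids in the first column.  Duplicate gene identifiers are
    disambiguated by suffixing; duplicate cell barcodes are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "tsv"

    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = _dedupe([str(g) for g in df.columns], "gene ids")
        return CountMatrix(df.to_numpy(dtype=np.float64), [str(c) for c in df.index], genes)
    raise ValueError(f"unknown format {format!r}")


def _find_one(d: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for cand in (d / stem, d / (stem + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {stems} found in {d}")


def _read_mtx_dir(d: Path, cells_as_rows: bool = False) -> CountMatrix:
    mtx = _find_one(d, ["matrix.mtx"])
    barcodes = _find_one(d, ["barcodes.tsv", "barcodes.txt"])
    features = _find_one(d, ["features.tsv", "genes.tsv", "features.txt", "genes.txt"])
    try:
        mat = spio.mmread(mtx)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise ValueError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    mat = np.asarray(sparse.coo_matrix(mat).todense(), dtype=np.float64)
    if not cells_as_rows:
        mat = mat.T  # genes x cells on disk -> cells x genes
    cell_ids = _read_id_column(barcodes)
    # 10x features.tsv carries (id, symbol, type); use the symbol column
    gene_ids = _dedupe(_read_id_column(features, prefer_second=True), "gene ids")
    return CountMatrix(mat, cell_ids, gene_ids)


def write_counts(m: CountMatrix, path: str | Path, format: str = "mtx_dir") -> None:
    """Write a CountMatrix in the same formats :func:`read_counts` consumes."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(m.values.T))
        (path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids)
        )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (cell_id, type) delimited file into a mapping.

    A cell listed twice with conflicting types is an error; an empty file
    yields an empty mapping with a warning.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        logger.warning("label file %s is empty", path)
        return {}
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t") if "\t" in line else line.split(",")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        cell, typ = parts[0].strip(), parts[1].strip()
        if lineno == 1 and cell.lower() in ("cell_id", "cell", "barcode"):
            continue
        if cell in out and out[cell] != typ:
            raise ValueError(f"cell {cell!r} labeled both {out[cell]!r} and {typ!r}")
        out[cell] = typ
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{t}\n" for c, t in labels.items()))


def read_ortholog_map(path: str | Path, policy: str = "drop_ambiguous") -> OrthologMap:
    """Read a two-column (source_gene, target_gene) file.

    Many-to-many rows are resolved per *policy*: ``drop_ambiguous`` removes
    every source gene that maps to more than one target; ``first`` keeps the
    first target in file order.  Zero usable rows is an error.
    """
    if policy not in ("drop_ambiguous", "first"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    rows: list[tuple[str, str]] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) >= 2 and parts[0].strip() and parts[1].strip():
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ValueError(f"no usable ortholog rows in {path}")
    mapping: dict[str, str] = {}
    ambiguous: set[str] = set()
    for src, tgt in rows:
        if src in mapping and mapping[src] != tgt:
            ambiguous.add(src)
        else:
            mapping.setdefault(src, tgt)
    if policy == "drop_ambiguous":
        for src in ambiguous:
            del mapping[src]
    n_dropped = len(ambiguous) if policy == "drop_ambiguous" else 0
    logger.info(
        "ortholog map: %d rows -> %d resolved entries (%d ambiguous sources %s)",
        len(rows), len(mapping), len(ambiguous),
        "dropped" if policy == "drop_ambiguous" else "kept first",
    )
    return OrthologMap(mapping, n_input_rows=len(rows), n_dropped_ambiguous=n_dropped)


def write_ortholog_map(om: OrthologMap, path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\t{t}\n" for s, t in om.mapping.items()))


# ---------------------------------------------------------------------------
# gene-space alignment


def align_to_gene_space(
    m: CountMatrix,
    gene_space: Sequence[str],
    ortholog_map: OrthologMap | None = None,
    case_fold: bool = False,
) -> CountMatrix:
    """Project a count matrix onto a model's frozen gene space.

    Output columns are exactly *gene_space* in order.  Genes of the space
    absent from *m* (or with no ortholog) are zero-filled; genes of *m*
    outside the space are dropped; counts of matched genes are preserved.
    If an ortholog map is given, *m*'s gene ids are first translated from
    the source namespace into the space's namespace.

    Matching is by exact identifier string; ``case_fold=True`` lowercases
    both sides first.
    """
    gene_space = [str(g) for g in gene_space]
    _check_unique(gene_space, "gene-space ids")

    def fold(g: str) -> str:
        return g.lower() if case_fold else g

    src_names = m.gene_ids
    if ortholog_map is not None:
        omap = {fold(s): t for s, t in ortholog_map.mapping.items()}
        translated = [omap.get(fold(g)) for g in src_names]
    else:
        translated = [g for g in src_names]

    # first occurrence wins if translation collides two source genes
    col_of: dict[str, int] = {}
    for j, name in enumerate(translated):
        if name is not None and fold(name) not in col_of:
            col_of[fold(name)] = j

    out = np.zeros((m.n_cells, len(gene_space)), dtype=np.float64)
    n_matched = 0
    for k, g in enumerate(gene_space):
        j = col_of.get(fold(g))
        if j is not None:
            out[:, k] = m.values[:, j]
            n_matched += 1
    if n_matched == 0:
        raise ValueError(
            "no overlap between the query's (mapped) genes and the model gene "
            "space; annotation would be meaningless"
        )
    frac_zero_filled = 1.0 - n_matched / len(gene_space)
    logger.info(
        "aligned %d/%d gene-space genes (%.1f%% zero-filled)",
        n_matched, len(gene_space), 100 * frac_zero_filled,
    )
    return CountMatrix(out, list(m.cell_ids), gene_space)


# ---------------------------------------------------------------------------
# model bundle serialization


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Write a model bundle as a directory (weights, gene space, config,
    reference embeddings, history)."""
    from . import siamese  # local import avoids a cycle

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model = bundle.model
    ref = bundle.reference

    np.savez(path / "weights.npz", **{
        f"W{i}": W for i, (W, _) in enumerate(model.weights)
    }, **{
        f"b{i}": b for i, (_, b) in enumerate(model.weights)
    })
    np.savez(
        path / "reference.npz",
        embeddings=ref.embeddings,
        labels=np.asarray(ref.labels, dtype=object),
        cell_ids=np.asarray(ref.cell_ids, dtype=object),
    )
    meta = {
        "format_version": bundle.version,
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden_widths": list(model.spec.hidden_widths),
            "embedding_dim": model.spec.embedding_dim,
            "dropout_rate": model.spec.dropout_rate,
            "activation": model.spec.activation,
        },
        "config": (vars(model.config).copy() if model.config is not None else None),
        "gene_space": list(model.gene_space) if model.gene_space is not None else None,
        "best_epoch": model.best_epoch,
        "meta": bundle.meta,
    }
    (path / "bundle.json").write_text(json.dumps(meta, indent=1))
    if model.history is not None:
        model.history.to_csv(path / "history.tsv", sep="\t", index=False)


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle written by :func:`save_bundle`; round-trips embeddings
    bit-exactly (float64 stored losslessly)."""
    from . import annotate, siamese

    path = Path(path)
    meta_file = path / "bundle.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"{path} is not a model bundle (no bundle.json)")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted bundle metadata in {meta_file}: {exc}") from exc
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleVersionError(
            f"bundle format {version!r} is incompatible with this build "
            f"(expected {BUNDLE_FORMAT_VERSION!r})"
        )
    spec = siamese.NetworkSpec(**meta["spec"])
    with np.load(path / "weights.npz") as z:
        n_layers = sum(1 for k in z.files if k.startswith("W"))
        weights = [(z[f"W{i}"].copy(), z[f"b{i}"].copy()) for i in range(n_layers)]
    cfg = siamese.TrainConfig(**meta["config"]) if meta.get("config") else None
    history = None
    if (path / "history.tsv").exists():
        history = pd.read_csv(path / "history.tsv", sep="\t")
    model = siamese.TrainedModel(
        spec=spec,
        weights=weights,
        gene_space=tuple(meta["gene_space"]) if meta.get("gene_space") else None,
        config=cfg,
        history=history,
        best_epoch=meta.get("best_epoch"),
    )
    with np.load(path / "reference.npz", allow_pickle=True) as z:
        ref = annotate.ReferenceSet(
            embeddings=z["embeddings"].copy(),
            labels=[str(x) for x in z["labels"]],
            cell_ids=[str(x) for x in z["cell_ids"]],
        )
    return ModelBundle(model=model, reference=ref, version=version, meta=meta.get("meta", {}))
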