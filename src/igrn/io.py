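"""Readers, writers and validated in-memory containers.

Every external representation the pipeline touches goes through this
module: gene x cell count matrices (MatrixMarket triplet layout or dense
TSV), per-cell annotation tables, prior-knowledge edge tables
(ligand-receptor, receptor-TF, TF-target), gene genomic positions,
spatial coordinates, and the multilayer network output (edge TSV / JSON).

Conventions
-----------
* Gene symbols are harmonized by uppercasing only; no alias resolution.
* Duplicate gene rows are collapsed by summing counts (logged).
* MatrixMarket files are 1-based on disk; all in-memory indices 0-based.
* TSV means tab-separated, UTF-8, header required, no quoting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("igrn")

CELL_GROUPS = ("normal", "tumor")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x cells raw counts.

    ``counts`` is kept as a CSR sparse matrix so that row/column slicing
    and nonzero iteration never densify. Gene symbols and barcodes are
    unique and ordered.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in CountMatrix")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes in CountMatrix")
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValueError("non-integer counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def subset_cells(self, barcodes: Iterable[str]) -> "CountMatrix":
        idx = self.barcode_index()
        keep = [idx[b] for b in barcodes]
        return CountMatrix(list(self.genes), [self.barcodes[i] for i in keep],
                           self.counts[:, keep])


@dataclass
class NormalizedMatrix:
    """Genes x cells log-transformed size-normalized expression (>= 0).

    Same labels/shape contract as :class:`CountMatrix`; a cell whose raw
    counts are all zero maps to an all-zero column.
    """

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("normalized matrix shape inconsistent with labels")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValueError("non-finite normalized values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class GenePositions:
    """Genomic location of each gene plus a declared chromosome order.

    The chromosome order is the order of first appearance in the source
    table (never alphabetic, which would sort chr10 before chr2).
    """

    table: pd.DataFrame  # columns: gene, chromosome, start, end
    chrom_order: list[str]

    def __post_init__(self) -> None:
        required = {"gene", "chromosome", "start", "end"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"gene position table needs columns {sorted(required)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("duplicate genes in position table")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene with start > end")

    def chrom_rank(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chrom_order)}


@dataclass
class PriorKnowledge:
    """The three prior edge layers that bound the multilayer scaffold."""

    lr_pairs: set[tuple[str, str]]
    rtf_links: set[tuple[str, str]]
    tft_priors: set[tuple[str, str]]
    tft_motif: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, tg in self.tft_priors:
            if tf == tg:
                raise ValueError(f"self-loop in TF-target priors: {tf}")
        if not self.tft_motif:
            self.tft_motif = {p: True for p in self.tft_priors}


@dataclass
class SpatialTable:
    """Planar coordinates of spots or mapped cells."""

    table: pd.DataFrame  # columns: unit_id, x, y [, label]

    def __post_init__(self) -> None:
        required = {"unit_id", "x", "y"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"spatial table needs columns {sorted(required)}")
        if self.table["unit_id"].duplicated().any():
            raise ValueError("duplicate unit IDs in spatial table")
        if not np.isfinite(self.table[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("non-finite coordinates")
        self.table = self.table.reset_index(drop=True)

    def subset(self, unit_ids: Iterable[str]) -> "SpatialTable":
        ids = set(unit_ids)
        return SpatialTable(self.table[self.table["unit_id"].isin(ids)].copy())

    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _collapse_duplicate_genes(genes: list[str], counts: sp.spmatrix) -> tuple[list[str], sp.csr_matrix]:
    """Sum rows sharing a (case-folded) symbol; keep first-appearance order."""
    upper = [g.upper() for g in genes]
    if len(set(upper)) == len(upper):
        return upper, sp.csr_matrix(counts)
    order: list[str] = []
    seen: dict[str, int] = {}
    for g in upper:
        if g not in seen:
            seen[g] = len(order)
            order.append(g)
    rows = np.array([seen[g] for g in upper])
    indicator = sp.csr_matrix(
        (np.ones(len(upper)), (rows, np.arange(len(upper)))),
        shape=(len(order), len(upper)),
    )
    collapsed = sp.csr_matrix(indicator @ counts)
    n_dup = len(upper) - len(order)
    logger.info("collapsed %d duplicate gene row(s) by summing counts", n_dup)
    return order, collapsed


def read_counts(path: str | Path, format: str = "mtx_triplet") -> CountMatrix:
    """Read a gene x cell count matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: a directory containing ``matrix.mtx``,
        ``genes.tsv`` (or ``features.tsv``) and ``barcodes.tsv``.
        For ``dense_tsv``: a TSV file, first column gene symbols, header
        row barcodes.
    format
        ``mtx_triplet`` or ``dense_tsv``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        if not genes_f.exists():
            genes_f = path / "features.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise FileNotFoundError(f"missing companion file: {f}")
        counts = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = [line.split("\t")[0].strip() for line in
                 genes_f.read_text().strip().splitlines()]
        barcodes = [line.strip() for line in
                    barcodes_f.read_text().strip().splitlines()]
        if counts.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match gene/barcode "
                f"lists ({len(genes)}, {len(barcodes)})"
            )
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        barcodes = [str(b) for b in df.columns]
        counts = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown count format: {format}")

    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise ValueError("non-integer entries in count matrix")
    counts = sp.csr_matrix(counts.astype(np.int64))
    genes, counts = _collapse_duplicate_genes(genes, counts)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes")
    return CountMatrix(genes, barcodes, counts)


def write_counts(m: CountMatrix, path: str | Path, format: str = "mtx_triplet") -> None:
    """Write a count matrix in a format :func:`read_counts` can read back."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
        (path / "genes.tsv").write_text("".join(g + "\n" for g in m.genes))
        (path / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    elif format == "dense_tsv":
        df = pd.DataFrame(np.asarray(m.counts.todense()), index=m.genes,
                          columns=m.barcodes)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count format: {format}")


# ---------------------------------------------------------------------------
# cell annotation table
# ---------------------------------------------------------------------------

def validate_cell_table(cells: pd.DataFrame,
                        matrix: CountMatrix | NormalizedMatrix | None = None) -> pd.DataFrame:
    """Check the per-cell metadata contract.

    Required columns: barcode, sample, group (normal/tumor), cell_type.
    Optional: subcluster, trajectory_state. Barcodes must be unique and,
    if a matrix is supplied, a subset of its barcodes.
    """
    required = {"barcode", "sample", "group", "cell_type"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    if cells["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in cell table")
    bad = set(cells["group"].unique()) - set(CELL_GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if cells["cell_type"].isna().any() or (cells["cell_type"] == "").any():
        raise ValueError("empty cell_type labels")
    if matrix is not None:
        extra = set(cells["barcode"]) - set(matrix.barcodes)
        if extra:
            raise ValueError(f"{len(extra)} cell-table barcodes absent from matrix")
    return cells


def read_cell_table(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_table(cells)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _read_edge_tsv(path: str | Path, col_a: str, col_b: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (col_a, col_b):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df.empty:
        logger.warning("%s: empty prior table", path)
    df[col_a] = df[col_a].str.upper()
    df[col_b] = df[col_b].str.upper()
    return df


def read_priors(lr_path: str | Path, rtf_path: str | Path,
                tft_path: str | Path) -> PriorKnowledge:
    """Read the three prior edge tables.

    Expected headers: ``ligand``/``receptor``; ``receptor``/``tf``
    (optional ``pathway``); ``tf``/``target`` (optional ``motif``, truthy
    values mark motif support). Symbols are uppercased and rows
    deduplicated; TF-target self-loops are dropped with a warning.
    """
    lr = _read_edge_tsv(lr_path, "ligand", "receptor")
    rtf = _read_edge_tsv(rtf_path, "receptor", "tf")
    tft = _read_edge_tsv(tft_path, "tf", "target")

    lr_pairs = set(zip(lr["ligand"], lr["receptor"]))
    rtf_links = set(zip(rtf["receptor"], rtf["tf"]))

    tft_priors: set[tuple[str, str]] = set()
    tft_motif: dict[tuple[str, str], bool] = {}
    has_motif = "motif" in tft.columns
    for _, row in tft.iterrows():
        pair = (row["tf"], row["target"])
        if pair[0] == pair[1]:
            logger.warning("dropping TF-target self-loop: %s", pair[0])
            continue
        tft_priors.add(pair)
        flag = True
        if has_motif:
            flag = str(row["motif"]).strip().lower() in {"1", "true", "yes", "t"}
        # motif evidence wins over a duplicate row without it
        tft_motif[pair] = tft_motif.get(pair, False) or flag
    logger.info("priors: %d L-R, %d R-TF, %d TF-target",
                len(lr_pairs), len(rtf_links), len(tft_priors))
    return PriorKnowledge(lr_pairs, rtf_links, tft_priors, tft_motif)


def write_priors(priors: PriorKnowledge, lr_path: str | Path,
                 rtf_path: str | Path, tft_path: str | Path) -> None:
    pd.DataFrame(sorted(priors.lr_pairs), columns=["ligand", "receptor"]).to_csv(
        lr_path, sep="\t", index=False)
    pd.DataFrame(sorted(priors.rtf_links), columns=["receptor", "tf"]).to_csv(
        rtf_path, sep="\t", index=False)
    rows = [(tf, tg, int(priors.tft_motif.get((tf, tg), True)))
            for tf, tg in sorted(priors.tft_priors)]
    pd.DataFrame(rows, columns=["tf", "target", "motif"]).to_csv(
        tft_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene positions, spatial coordinates
# ---------------------------------------------------------------------------

def read_gene_positions(path: str | Path) -> GenePositions:
    """Read a gene-position TSV (gene, chromosome, start, end).

    Chromosome sort order is the order of first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene": str, "chromosome": str})
    missing = {"gene", "chromosome", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene position table missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].str.upper()
    chrom_order = list(dict.fromkeys(df["chromosome"]))
    return GenePositions(df, chrom_order)


def write_gene_positions(positions: GenePositions, path: str | Path) -> None:
    positions.table.to_csv(path, sep="\t", index=False)


def read_spatial(path: str | Path) -> SpatialTable:
    df = pd.read_csv(path)
    df["unit_id"] = df["unit_id"].astype(str)
    return SpatialTable(df)


def write_spatial(spatial: SpatialTable, path: str | Path) -> None:
    spatial.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

EDGE_TSV_COLUMNS = ["source", "target", "layer", "sender_population",
                    "receiver_population", "score"]


def write_igrn(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a multilayer network as an edge TSV or a JSON object.

    The edge TSV has exactly the columns (source, target, layer,
    sender_population, receiver_population, score); JSON carries the node
    roles and the stage as well and round-trips losslessly.
    """
    network.validate()
    path = Path(path)
    if format == "edge_tsv":
        rows = [
            {"source": e.source, "target": e.target, "layer": e.layer,
             "sender_population": network.sender,
             "receiver_population": network.receiver,
             "score": "" if e.score is None else repr(e.score)}
            for e in network.sorted_edges()
        ]
        df = pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        obj = {
            "sender": network.sender,
            "receiver": network.receiver,
            "stage": network.stage,
            "nodes": [{"name": n, "role": r}
                      for n, r in sorted(network.nodes.items())],
            "edges": [{"source": e.source, "target": e.target,
                       "layer": e.layer, "score": e.score}
                      for e in network.sorted_edges()],
        }
        path.write_text(json.dumps(obj, indent=1) + "\n")
    else:
        raise ValueError(f"unknown network format: {format}")


def read_igrn(path: str | Path, format: str = "json", stage: str = "pruned"):
    """Read a network written by :func:`write_igrn`.

    The edge TSV does not carry the stage, so ``stage`` supplies it;
    JSON ignores the argument.
    """
    from .network import IGRN, Edge, ROLE_BY_LAYER

    path = Path(path)
    if format == "json":
        obj = json.loads(path.read_text())
        nodes = {d["name"]: d["role"] for d in obj["nodes"]}
        edges = [Edge(d["source"], d["target"], d["layer"], d["score"])
                 for d in obj["edges"]]
        return IGRN(nodes=nodes, edges=edges, sender=obj["sender"],
                    receiver=obj["receiver"], stage=obj["stage"])
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        nodes: dict[str, str] = {}
        edges = []
        sender = receiver = ""
        for _, row in df.iterrows():
            layer = row["layer"]
            src_role, dst_role = ROLE_BY_LAYER[layer]
            nodes.setdefault(row["source"], src_role)
            nodes.setdefault(row["target"], dst_role)
            score = row["score"]
            score = None if pd.isna(score) else float(score)
            edges.append(Edge(row["source"], row["target"], layer, score))
            sender = row["sender_population"]
            receiver = row["receiver_population"]
        return IGRN(nodes=nodes, edges=edges, sender=sender,
                    receiver=receiver, stage=stage)
    raise ValueError(f"unknown network format: {format}")
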