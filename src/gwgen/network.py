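"""Candidate genome-wide genetic and epigenetic networks (GWGENs) and expression data.

A GWGEN is the union of a protein-protein interaction network (PPIN) over
protein-class nodes (proteins, transcription factors, receptors) and a gene
regulatory network (GRN) in which TFs, lncRNAs and miRNAs regulate genes,
lncRNAs and miRNAs.  A *candidate* GWGEN is binary: an edge is present or
absent, with no weight.  Edge weights (interaction/regulation abilities) only
appear after system identification, on the *real* GWGEN.

File dialect for all loaders: tab-separated, UTF-8, ``#`` comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger("gwgen")

NodeClass = Literal["protein", "TF", "receptor", "lncRNA", "miRNA", "gene"]

#: node classes that take part in protein-protein interactions
PROTEIN_CLASSES = frozenset({"protein", "TF", "receptor"})
#: node classes allowed as sources of directed regulations
REGULATOR_CLASSES = frozenset({"TF", "lncRNA", "miRNA"})
#: node classes allowed as targets of directed regulations
TARGET_CLASSES = frozenset({"gene", "lncRNA", "miRNA"})
VALID_CLASSES = frozenset({"protein", "TF", "receptor", "lncRNA", "miRNA", "gene"})


@dataclass(frozen=True)
class NodeRecord:
    """A typed network node.

    TF and receptor are protein subclasses: a TF interacts in the PPIN like
    any protein and additionally acts as a transcriptional regulator.
    """

    id: str
    symbol: str
    node_class: str

    def __post_init__(self) -> None:
        if self.node_class not in VALID_CLASSES:
            raise ValueError(f"unknown node_class {self.node_class!r} for node {self.id!r}")

    @property
    def is_protein_like(self) -> bool:
        return self.node_class in PROTEIN_CLASSES


@dataclass
class CandidateGWGEN:
    """Binary candidate network: typed nodes, undirected PPI edges, directed regulations.

    ``ppi_edges`` holds id pairs stored sorted (undirected, deduplicated);
    ``reg_edges`` holds directed ``(source, target)`` pairs.  Self edges are
    never stored: they are dropped at load time with a warning.
    """

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    ppi_edges: set[tuple[str, str]] = field(default_factory=set)
    reg_edges: set[tuple[str, str]] = field(default_factory=set)

    def node(self, node_id: str) -> NodeRecord:
        return self.nodes[node_id]

    def add_node(self, record: NodeRecord) -> None:
        existing = self.nodes.get(record.id)
        if existing is not None and existing != record:
            raise ValueError(f"conflicting records for node {record.id!r}")
        self.nodes[record.id] = record

    def add_ppi_edge(self, a: str, b: str) -> bool:
        """Add an undirected PPI edge; returns False for dropped self edges."""
        if a == b:
            logger.warning("dropping self PPI edge %s-%s", a, b)
            return False
        for end in (a, b):
            if end not in self.nodes:
                raise KeyError(f"PPI endpoint {end!r} absent from node table")
            if not self.nodes[end].is_protein_like:
                raise ValueError(
                    f"PPI endpoint {end!r} has class {self.nodes[end].node_class!r},"
                    " expected a protein-class node"
                )
        self.ppi_edges.add((min(a, b), max(a, b)))
        return True

    def add_reg_edge(self, source: str, target: str) -> bool:
        """Add a directed regulation; returns False for dropped self edges."""
        if source == target:
            logger.warning("dropping self regulation %s->%s", source, target)
            return False
        for end in (source, target):
            if end not in self.nodes:
                raise KeyError(f"regulation endpoint {end!r} absent from node table")
        src_class = self.nodes[source].node_class
        tgt_class = self.nodes[target].node_class
        if src_class not in REGULATOR_CLASSES:
            raise ValueError(f"regulation source {source!r} has class {src_class!r}")
        if tgt_class not in TARGET_CLASSES:
            raise ValueError(f"regulation target {target!r} has class {tgt_class!r}")
        self.reg_edges.add((source, target))
        return True

    # -- per-node candidate sets ------------------------------------------------

    def ppi_partners(self, node_id: str) -> list[str]:
        """Sorted candidate interactors of a protein-class node (size G_q)."""
        out = set()
        for a, b in self.ppi_edges:
            if a == node_id:
                out.add(b)
            elif b == node_id:
                out.add(a)
        return sorted(out)

    def regulators_of(self, node_id: str) -> dict[str, list[str]]:
        """Sorted candidate regulators of a target node, split by class.

        Returns ``{"TF": [...], "lncRNA": [...], "miRNA": [...]}`` whose sizes
        are the candidate regulation orders (U, V, W).
        """
        out: dict[str, list[str]] = {"TF": [], "lncRNA": [], "miRNA": []}
        for source, target in self.reg_edges:
            if target == node_id:
                out[self.nodes[source].node_class].append(source)
        return {k: sorted(v) for k, v in out.items()}

    def nodes_of_class(self, classes: Iterable[str]) -> list[str]:
        wanted = set(classes)
        return sorted(nid for nid, rec in self.nodes.items() if rec.node_class in wanted)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in sorted(VALID_CLASSES)}
        for rec in self.nodes.values():
            counts[rec.node_class] += 1
        return counts


@dataclass(frozen=True)
class CandidateSets:
    """Candidate interactor/regulator sets of one node.

    For a protein-class node only ``interactors`` is populated (its size is
    the candidate interaction order G_q); for a gene/lncRNA/miRNA target the
    TF/lncRNA/miRNA regulator lists have sizes (U, V, W).
    """

    node_id: str
    node_class: str
    interactors: tuple[str, ...] = ()
    tfs: tuple[str, ...] = ()
    lncrnas: tuple[str, ...] = ()
    mirnas: tuple[str, ...] = ()

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.interactors), len(self.tfs), len(self.lncrnas), len(self.mirnas))

    @property
    def all_regulators(self) -> tuple[str, ...]:
        return self.tfs + self.lncrnas + self.mirnas


def candidate_sets(network: CandidateGWGEN, node_id: str) -> CandidateSets:
    """Candidate interactors (PPIN) or regulators (GRN) of a node.

    A TF is protein-like, so it receives an interactor set; targets of
    regulations (gene/lncRNA/miRNA) receive regulator sets.  lncRNA and miRNA
    nodes are both PPIN-free and receive regulator sets only.
    """
    rec = network.node(node_id)
    if rec.is_protein_like:
        return CandidateSets(
            node_id=node_id,
            node_class=rec.node_class,
            interactors=tuple(network.ppi_partners(node_id)),
        )
    regs = network.regulators_of(node_id)
    return CandidateSets(
        node_id=node_id,
        node_class=rec.node_class,
        tfs=tuple(regs["TF"]),
        lncrnas=tuple(regs["lncRNA"]),
        mirnas=tuple(regs["miRNA"]),
    )


# -- expression data ------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Node x sample expression matrix with per-sample phenotype labels.

    Rows are nodes, columns are samples; ``group_labels`` maps each sample id
    to a phenotype group (typically ``case`` / ``control``).  Proteins and
    their transcripts share one node id and hence one expression row.
    """

    expression: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.expression.columns if s not in self.group_labels.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.group_labels = self.group_labels.loc[self.expression.columns]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_labels.unique())

    def samples_in_group(self, group: str | None) -> list[str]:
        if group is None:
            return self.sample_ids
        mask = self.group_labels == group
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return list(self.group_labels.index[mask])

    def values(self, node_id: str, group: str | None = None) -> np.ndarray:
        """Expression of one node over the samples of a group (or all)."""
        if node_id not in self.expression.index:
            raise KeyError(f"node {node_id!r} has no expression row")
        return self.expression.loc[node_id, self.samples_in_group(group)].to_numpy(dtype=float)

    def subset(self, group: str) -> "ExpressionDataset":
        cols = self.samples_in_group(group)
        return ExpressionDataset(self.expression[cols].copy(), self.group_labels.loc[cols].copy())


# -- file IO --------------------------------------------------------------------

_READ_KW = dict(sep="\t", comment="#", dtype=str)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_candidate_network(
    ppi_path: str | Path | None,
    grn_path: str | Path | None,
    node_table: str | Path,
) -> CandidateGWGEN:
    """Load a candidate GWGEN from node/PPI/regulation TSV files.

    ``nodes.tsv`` columns: id, symbol, node_class.  ``ppi.tsv`` columns:
    source, target.  ``grn.tsv`` columns: source, target.  Either edge file
    may be None or empty (nodes-only network).  Unknown node classes and edge
    endpoints absent from the node table are rejected with the offending
    line; duplicate edges (including A-B vs B-A PPI listings) collapse to one.
    """
    net = CandidateGWGEN()
    nodes = _read_table(node_table, ["id", "symbol", "node_class"])
    for i, row in enumerate(nodes.itertuples(index=False), start=2):
        if row.node_class not in VALID_CLASSES:
            raise ValueError(
                f"{node_table}: line {i}: unknown node_class {row.node_class!r}"
            )
        net.add_node(NodeRecord(id=row.id, symbol=row.symbol, node_class=row.node_class))

    def _load_edges(path, adder, kind):
        if path is None:
            return
        df = _read_table(path, ["source", "target"])
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                adder(row.source, row.target)
            except (KeyError, ValueError) as exc:
                raise type(exc)(f"{path}: line {i}: {exc}") from exc
        logger.info("loaded %d %s edges from %s", len(df), kind, path)

    _load_edges(ppi_path, net.add_ppi_edge, "PPI")
    _load_edges(grn_path, net.add_reg_edge, "regulation")
    logger.info(
        "candidate GWGEN: %d nodes (%s), %d PPI edges, %d regulations",
        len(net.nodes),
        ", ".join(f"{k}={v}" for k, v in net.class_counts().items() if v),
        len(net.ppi_edges),
        len(net.reg_edges),
    )
    return net


def write_candidate_network(
    network: CandidateGWGEN,
    nodes_path: str | Path,
    ppi_path: str | Path,
    grn_path: str | Path,
) -> None:
    """Write a candidate GWGEN in the same dialect the loader reads (round-trip safe)."""
    recs = sorted(network.nodes.values(), key=lambda r: r.id)
    pd.DataFrame(
        {"id": [r.id for r in recs], "symbol": [r.symbol for r in recs],
         "node_class": [r.node_class for r in recs]}
    ).to_csv(nodes_path, sep="\t", index=False)
    ppi = sorted(network.ppi_edges)
    pd.DataFrame({"source": [a for a, _ in ppi], "target": [b for _, b in ppi]}).to_csv(
        ppi_path, sep="\t", index=False
    )
    grn = sorted(network.reg_edges)
    pd.DataFrame({"source": [a for a, _ in grn], "target": [b for _, b in grn]}).to_csv(
        grn_path, sep="\t", index=False
    )


def load_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    zscore: bool = False,
) -> ExpressionDataset:
    """Load an expression matrix (rows nodes, columns samples) and group labels.

    ``expr.tsv``: first column node ids, remaining columns one per sample.
    ``labels.tsv`` columns: sample, group.  Every matrix sample must be
    labelled.  ``zscore`` optionally standardizes each node row (off by
    default; fits run on raw expression).
    """
    expr = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    expr.index.name = None
    labels_df = _read_table(labels_path, ["sample", "group"])
    labels = pd.Series(labels_df["group"].values, index=labels_df["sample"].values)
    unlabeled = [s for s in expr.columns if s not in labels.index]
    if unlabeled:
        raise ValueError(f"{matrix_path}: samples without labels in {labels_path}: {unlabeled}")
    ds = ExpressionDataset(expr.astype(float), labels)
    if zscore:
        mat = ds.expression
        sd = mat.std(axis=1, ddof=0).replace(0.0, 1.0)
        ds = ExpressionDataset(mat.sub(mat.mean(axis=1), axis=0).div(sd, axis=0), ds.group_labels)
    sizes = ds.group_labels.value_counts().to_dict()
    logger.info("expression: %d nodes x %d samples, groups %s", *ds.expression.shape, sizes)
    return ds


def write_expression(
    dataset: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    dataset.expression.to_csv(matrix_path, sep="\t", index_label="node")
    pd.DataFrame(
        {"sample": dataset.group_labels.index, "group": dataset.group_labels.values}
    ).to_csv(labels_path, sep="\t", index=False)
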