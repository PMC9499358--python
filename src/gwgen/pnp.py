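"""Principal network projection (PNP): core-network extraction by SVD.

The real GWGEN's estimated abilities are arranged in a network matrix H with
one row per node (proteins first — TFs and receptors live in the protein
block — then genes, lncRNAs, miRNAs) and one column per possible source
(protein interactors/TFs, then lncRNAs, then miRNAs); absent edges are
zero-padded.  H = S V D^T is decomposed by SVD, each singular value's share
of the total squared spectrum is its normalized energy E_i = v_i^2 / sum v^2,
and the minimal leading set of singular vectors whose cumulative energy
reaches the threshold (0.85) is retained.  Every node (row h_a) is projected
onto the retained right singular vectors, Z(a,b) = h_a . d_b, and scored by
the two-norm S(a) = sqrt(sum_b Z(a,b)^2); the top-K nodes by score induce
the core GWGEN (K = 6000 by default, capped at the node count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .order_detection import RealGWGEN, WeightedEdge

logger = logging.getLogger("gwgen")

DEFAULT_ENERGY_THRESHOLD = 0.85
DEFAULT_CORE_SIZE = 6000

_ROW_BLOCKS = (("protein", "TF", "receptor"), ("gene",), ("lncRNA",), ("miRNA",))
_COL_BLOCKS = (("protein", "TF", "receptor"), ("lncRNA",), ("miRNA",))


@dataclass
class NetworkMatrix:
    """Dense ability matrix of a real GWGEN with deterministic index ordering."""

    H: np.ndarray
    row_index: list[str]
    col_index: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape


@dataclass
class ProjectionResult:
    singular_values: np.ndarray
    energies: np.ndarray
    retained: int
    Z: np.ndarray  # node x retained projection values
    scores: np.ndarray  # two-norm projection value per node
    row_index: list[str] = field(default_factory=list)

    def score_of(self, node_id: str) -> float:
        return float(self.scores[self.row_index.index(node_id)])


def _block_ids(nodes: dict, blocks) -> list[str]:
    out: list[str] = []
    for classes in blocks:
        wanted = set(classes)
        out.extend(sorted(nid for nid, rec in nodes.items() if rec.node_class in wanted))
    return out


def assemble_network_matrix(real_gwgen: RealGWGEN) -> NetworkMatrix:
    """Zero-padded ability matrix H: rows class-blocked nodes, columns sources.

    Entry (target, source) holds the fitted ability of the source on the
    target; PPI interactions appear once per fitted direction.  Nonzero
    entries correspond exactly to real-GWGEN edges.
    """
    rows = _block_ids(real_gwgen.nodes, _ROW_BLOCKS)
    cols = _block_ids(real_gwgen.nodes, _COL_BLOCKS)
    row_pos = {nid: i for i, nid in enumerate(rows)}
    col_pos = {nid: j for j, nid in enumerate(cols)}
    H = np.zeros((len(rows), len(cols)))
    for edge in real_gwgen.edges:
        try:
            a = row_pos[edge.target]
            b = col_pos[edge.source]
        except KeyError as exc:
            raise KeyError(f"edge endpoint {exc.args[0]!r} has no matrix index") from None
        H[a, b] = edge.ability
    return NetworkMatrix(H=H, row_index=rows, col_index=cols)


def svd_energy(
    H: np.ndarray, threshold: float = DEFAULT_ENERGY_THRESHOLD
) -> tuple[np.ndarray, np.ndarray, int]:
    """Singular values, normalized energies and the minimal retained count I.

    I = min{ k : sum_{i<=k} E_i >= threshold }, so the cumulative energy at
    I-1 is strictly below the threshold and at I is at or above it.
    """
    if not np.any(H):
        raise ValueError("degenerate network matrix: all abilities are zero")
    sv = np.linalg.svd(H, compute_uv=False)
    energies = sv**2 / float(np.sum(sv**2))
    cumulative = np.cumsum(energies)
    retained = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    retained = min(retained, len(sv))
    return sv, energies, retained


def project_nodes(
    H: np.ndarray,
    threshold: float = DEFAULT_ENERGY_THRESHOLD,
    row_index: list[str] | None = None,
) -> ProjectionResult:
    """Project every node row onto the retained right singular vectors.

    Z(a,b) = h_a . d_b for the b-th retained right singular vector d_b;
    S(a) = sqrt(sum_b Z(a,b)^2).  With all singular vectors retained S(a)
    equals the row two-norm.
    """
    sv, energies, retained = svd_energy(H, threshold)
    _, _, vt = np.linalg.svd(H, full_matrices=False)
    Z = H @ vt[:retained].T
    scores = np.sqrt(np.sum(Z**2, axis=1))
    return ProjectionResult(
        singular_values=sv,
        energies=energies,
        retained=retained,
        Z=Z,
        scores=scores,
        row_index=list(row_index) if row_index is not None else [],
    )


@dataclass
class CoreGWGEN:
    """Top-K node-induced subnetwork of a real GWGEN."""

    nodes: dict
    edges: list[WeightedEdge]
    scores: dict[str, float]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.nodes.values():
            counts[rec.node_class] = counts.get(rec.node_class, 0) + 1
        return dict(sorted(counts.items()))


def extract_core(
    real_gwgen: RealGWGEN,
    projection: ProjectionResult,
    core_size: int = DEFAULT_CORE_SIZE,
) -> CoreGWGEN:
    """Induce the core GWGEN on the top-scoring nodes.

    Keeps min(core_size, node count) nodes ranked by descending projection
    score with ties at the cutoff broken by node id, plus every surviving
    edge whose endpoints are both kept.
    """
    if not projection.row_index:
        raise ValueError("projection carries no row index; pass row_index to project_nodes")
    score_map = dict(zip(projection.row_index, projection.scores))
    missing = [nid for nid in real_gwgen.nodes if nid not in score_map]
    if missing:
        raise KeyError(f"nodes without projection scores: {missing[:5]}")
    k = min(core_size, len(real_gwgen.nodes))
    if core_size > len(real_gwgen.nodes):
        logger.info(
            "core size %d exceeds node count %d; returning the whole network",
            core_size, len(real_gwgen.nodes),
        )
    ranked = sorted(real_gwgen.nodes, key=lambda nid: (-score_map[nid], nid))
    kept = set(ranked[:k])
    nodes = {nid: real_gwgen.nodes[nid] for nid in kept}
    edges = [e for e in real_gwgen.edges if e.source in kept and e.target in kept]
    core = CoreGWGEN(
        nodes=nodes, edges=edges, scores={nid: float(score_map[nid]) for nid in kept}
    )
    logger.info("core GWGEN: %d nodes, class counts %s", len(nodes), core.class_counts())
    return core


def pnp(
    real_gwgen: RealGWGEN,
    threshold: float = DEFAULT_ENERGY_THRESHOLD,
    core_size: int = DEFAULT_CORE_SIZE,
) -> tuple[CoreGWGEN, ProjectionResult, NetworkMatrix]:
    """Full PNP pass: assemble H, project, and extract the core GWGEN."""
    matrix = assemble_network_matrix(real_gwgen)
    projection = project_nodes(matrix.H, threshold, row_index=matrix.row_index)
    core = extract_core(real_gwgen, projection, core_size)
    return core, projection, matrix
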