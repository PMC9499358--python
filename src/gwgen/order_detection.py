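"""System order detection: AIC subset selection and candidate-edge pruning.

The candidate GWGEN over-specifies every node's interaction/regulation order
(database edges include false positives).  For each node the true order is
detected by minimizing

    AIC = log(Omega) + 2 (O + 1) / N

over regulator subsets, where Omega is the mean squared residual of the
constrained least-squares fit, O the number of regressors kept and N the
sample count (natural log; the +1 counts the basal intercept).  Edges whose
regressor is not in the AIC-minimizing subset are pruned as false positives;
the survivors, annotated with their refit abilities, form the real GWGEN.

Subset search: exhaustive enumeration when a node has at most
``exhaustive_cap`` candidates (exact), greedy backward elimination beyond
that (scalable).  Ties in AIC are broken toward the smaller subset, then
lexicographically by regulator ids, so selection is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .identification import NodeModel, build_problem, fit_problem
from .network import CandidateGWGEN, CandidateSets, ExpressionDataset, candidate_sets

logger = logging.getLogger("gwgen")

OMEGA_FLOOR = 1e-12
DEFAULT_EXHAUSTIVE_CAP = 12


def aic_score(residual_error: float, order: int, n_samples: int) -> float:
    """AIC of a fitted node model: log(Omega) + 2 (order + 1) / N.

    A nonpositive residual error (perfect fit) is floored at 1e-12 so the
    log stays finite; the floor is flagged by the caller's trace.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    omega = max(float(residual_error), OMEGA_FLOOR)
    return float(np.log(omega) + 2.0 * (order + 1) / n_samples)


@dataclass
class OrderSelectionResult:
    """Outcome of AIC order detection for one node."""

    node_id: str
    node_class: str
    candidate_order: int
    selected_subset: tuple[str, ...]
    best_aic: float
    aic_trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    strategy: str = "exhaustive"
    model: NodeModel | None = None  # refit on the selected subset


def _subset_problem(full, subset: tuple[str, ...]):
    """Column-slice the full-candidate regression problem down to a subset."""
    from .identification import RegressionProblem

    keep = set(subset)
    idx = [
        j
        for j, (rid, kind) in enumerate(full.column_labels)
        if kind == "basal" or rid in keep
    ]
    return RegressionProblem(
        node_id=full.node_id,
        node_class=full.node_class,
        response=full.response,
        design=full.design[:, idx],
        constraint_mask=full.constraint_mask[idx],
        column_labels=[full.column_labels[j] for j in idx],
    )


def select_order(
    dataset: ExpressionDataset,
    network: CandidateGWGEN,
    node_id: str,
    strategy: str = "auto",
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
    group: str | None = None,
) -> OrderSelectionResult:
    """Detect a node's true interaction/regulation subset by AIC minimization.

    ``strategy``: ``"exhaustive"`` enumerates every regulator subset;
    ``"greedy_backward"`` starts from the full candidate set and removes the
    regressor whose removal most decreases AIC until no removal helps;
    ``"auto"`` picks exhaustive when the candidate order is within
    ``exhaustive_cap`` and greedy otherwise.
    """
    sets = candidate_sets(network, node_id)
    rec = network.node(node_id)
    candidates = sets.interactors if rec.is_protein_like else sets.all_regulators
    k = len(candidates)

    if strategy not in {"auto", "exhaustive", "greedy_backward"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    chosen = strategy
    if strategy == "auto":
        chosen = "exhaustive" if k <= exhaustive_cap else "greedy_backward"
    if chosen == "exhaustive" and k > exhaustive_cap:
        logger.warning(
            "%s: %d candidates exceed exhaustive cap %d; using greedy backward",
            node_id, k, exhaustive_cap,
        )
        chosen = "greedy_backward"

    n = len(dataset.samples_in_group(group))
    full_problem = build_problem(dataset, network, node_id, None, group, sets=sets)
    trace: list[tuple[tuple[str, ...], float]] = []
    best: tuple[float, int, tuple[str, ...], NodeModel] | None = None

    def _consider(subset: tuple[str, ...]) -> float:
        nonlocal best
        model = fit_problem(_subset_problem(full_problem, subset))
        aic = aic_score(model.residual_error, len(subset), model.n_samples)
        trace.append((subset, aic))
        key = (aic, len(subset), subset)
        if best is None or key < (best[0], best[1], best[2]):
            best = (aic, len(subset), subset, model)
        return aic

    if chosen == "exhaustive":
        for size in range(k + 1):
            for combo in combinations(candidates, size):
                _consider(combo)
    else:
        current = tuple(candidates)
        if n < k + 1:
            # design wider than the sample count: start from the largest
            # fittable nested model, ranking candidates by |marginal correlation|
            y = dataset.values(node_id, group)
            def _corr(c: str) -> float:
                x = dataset.values(c, group)
                sx, sy = np.std(x), np.std(y)
                if sx == 0 or sy == 0:
                    return 0.0
                return abs(float(np.corrcoef(x, y)[0, 1]))
            ranked = sorted(candidates, key=lambda c: (-_corr(c), c))
            current = tuple(sorted(ranked[: max(n - 1, 0)]))
            logger.warning(
                "%s: N=%d too small for %d candidates; greedy starts from %d",
                node_id, n, k, len(current),
            )
        current_aic = _consider(current)
        while current:
            removals = []
            for drop in current:
                reduced = tuple(c for c in current if c != drop)
                removals.append((_consider(reduced), reduced))
            removals.sort(key=lambda t: (t[0], len(t[1]), t[1]))
            if removals[0][0] < current_aic:
                current_aic, current = removals[0]
            else:
                break

    assert best is not None
    aic_best, _, subset_best, model_best = best
    return OrderSelectionResult(
        node_id=node_id,
        node_class=rec.node_class,
        candidate_order=k,
        selected_subset=subset_best,
        best_aic=aic_best,
        aic_trace=trace,
        strategy=chosen,
        model=model_best,
    )


# -- real GWGEN -----------------------------------------------------------------


@dataclass(frozen=True)
class WeightedEdge:
    """A surviving edge with its refit ability.

    ``kind`` is the regressor class of the source: ``"protein"`` for PPI
    interactions (the ability is the kappa of the fitted target node's
    equation, i.e. directional per fit), else ``"TF"``/``"lncRNA"``/``"miRNA"``.
    """

    source: str
    target: str
    kind: str
    ability: float


@dataclass
class RealGWGEN:
    """Data-supported network: candidate nodes plus AIC-surviving weighted edges."""

    nodes: dict  # node id -> NodeRecord (shared with the candidate network)
    edges: list[WeightedEdge] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.nodes.values():
            counts[rec.node_class] = counts.get(rec.node_class, 0) + 1
        return dict(sorted(counts.items()))

    def edge_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.kind] = counts.get(e.kind, 0) + 1
        return dict(sorted(counts.items()))

    def undirected_ppi_pairs(self) -> set[tuple[str, str]]:
        return {
            (min(e.source, e.target), max(e.source, e.target))
            for e in self.edges
            if e.kind == "protein"
        }

    def directed_regulations(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges if e.kind != "protein"}


def prune_network(
    candidate: CandidateGWGEN,
    selections: dict[str, OrderSelectionResult],
) -> RealGWGEN:
    """Prune candidate edges down to the AIC-selected subsets.

    A PPI pair q-r survives if r is selected in q's fit OR q in r's fit (each
    protein's equation is fitted independently; either detection keeps the
    interaction).  Each surviving direction contributes one weighted record
    carrying that fit's kappa.  A regulation survives iff the regulator is in
    its target's selected subset.  Nodes are never removed.
    """
    edges: list[WeightedEdge] = []
    for node_id, sel in sorted(selections.items()):
        model = sel.model
        if model is None:
            raise ValueError(f"selection for {node_id!r} carries no refit model")
        for rid in sel.selected_subset:
            edges.append(
                WeightedEdge(
                    source=rid,
                    target=node_id,
                    kind=model.coefficient_kinds[rid],
                    ability=model.coefficients[rid],
                )
            )
    real = RealGWGEN(nodes=dict(candidate.nodes), edges=edges)
    logger.info(
        "real GWGEN: %d nodes, edge counts %s", len(real.nodes), real.edge_counts()
    )
    return real


def identify_real_network(
    dataset: ExpressionDataset,
    network: CandidateGWGEN,
    group: str | None = None,
    strategy: str = "auto",
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> tuple[RealGWGEN, dict[str, OrderSelectionResult]]:
    """Run order detection over every fittable node and prune to the real GWGEN.

    Fittable nodes are those with an expression row: protein-class nodes are
    fitted against their candidate interactors, gene/lncRNA/miRNA nodes
    against their candidate regulators.  Nodes with no expression row are
    skipped with a warning (their edges cannot be supported by data).
    """
    selections: dict[str, OrderSelectionResult] = {}
    for node_id in sorted(network.nodes):
        if node_id not in dataset.expression.index:
            logger.warning("%s: no expression row; skipped", node_id)
            continue
        sets = candidate_sets(network, node_id)
        rec = network.node(node_id)
        n_cand = len(sets.interactors) if rec.is_protein_like else len(sets.all_regulators)
        if n_cand == 0:
            continue  # nothing to prune for isolated nodes
        selections[node_id] = select_order(
            dataset, network, node_id, strategy, exhaustive_cap, group
        )
    return prune_network(network, selections), selections
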