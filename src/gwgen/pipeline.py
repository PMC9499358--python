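"""End-to-end orchestration: assemble -> identify per group -> prune -> PNP -> compare.

Stage boundaries are plain-text file formats, so every stage can be rerun
standalone on the previous stage's outputs.  A run manifest (JSON) records
the configuration verbatim plus per-stage timings and counts; rerunning from
a manifest's configuration reproduces all deterministic outputs bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .network import CandidateGWGEN, load_candidate_network, load_expression
from .order_detection import (
    DEFAULT_EXHAUSTIVE_CAP,
    OrderSelectionResult,
    RealGWGEN,
    identify_real_network,
)
from .pnp import DEFAULT_CORE_SIZE, DEFAULT_ENERGY_THRESHOLD, CoreGWGEN, pnp

logger = logging.getLogger("gwgen")


@dataclass
class RunConfig:
    nodes_path: str
    ppi_path: str
    grn_path: str
    expr_path: str
    labels_path: str
    out_dir: str
    groups: tuple[str, ...] = ("control", "case")
    strategy: str = "auto"
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD
    core_size: int = DEFAULT_CORE_SIZE
    seed: int = 0  # reserved for the stochastic stages (DTI); the network stages are deterministic


def summarize_network(network: CandidateGWGEN | RealGWGEN | CoreGWGEN) -> dict:
    """Node and edge counts by class (Table-style bookkeeping block)."""
    if isinstance(network, CandidateGWGEN):
        return {
            "nodes": network.class_counts(),
            "edges": {"ppi": len(network.ppi_edges), "regulation": len(network.reg_edges)},
        }
    counts: dict[str, int] = {}
    for rec in network.nodes.values():
        counts[rec.node_class] = counts.get(rec.node_class, 0) + 1
    edge_counts: dict[str, int] = {}
    for e in network.edges:
        edge_counts[e.kind] = edge_counts.get(e.kind, 0) + 1
    return {"nodes": dict(sorted(counts.items())), "edges": dict(sorted(edge_counts.items()))}


def write_real_network(real: RealGWGEN | CoreGWGEN, path: str | Path) -> None:
    pd.DataFrame(
        [(e.source, e.target, e.kind, e.ability) for e in real.edges],
        columns=["source", "target", "edge_kind", "ability"],
    ).to_csv(path, sep="\t", index=False)


def write_order_report(selections: dict[str, OrderSelectionResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        for node_id in sorted(selections):
            sel = selections[node_id]
            fh.write(json.dumps({
                "node": node_id,
                "class": sel.node_class,
                "candidate_order": sel.candidate_order,
                "selected": list(sel.selected_subset),
                "best_aic": sel.best_aic,
                "strategy": sel.strategy,
            }) + "\n")


def _edge_key(e) -> tuple[str, str, str]:
    return (e.source, e.target, e.kind)


def run_pipeline(config: RunConfig) -> dict:
    """Run the network stages for every group and write all artifacts.

    Produces per-group real and core GWGEN TSVs, projection scores, an order
    report, a case-vs-control core-edge difference summary, and the run
    manifest (returned and written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def _stage(name):
        manifest["stages"][name] = {"started": time.time()}
        return time.time()

    def _done(name, t0, **info):
        manifest["stages"][name].update(elapsed_s=round(time.time() - t0, 3), **info)

    try:
        t0 = _stage("assemble")
        network = load_candidate_network(config.ppi_path, config.grn_path, config.nodes_path)
        dataset = load_expression(config.expr_path, config.labels_path)
        _done("assemble", t0, candidate=summarize_network(network),
              samples=dataset.group_labels.value_counts().to_dict())

        core_edges: dict[str, set] = {}
        core_nodes: dict[str, set] = {}
        for group in config.groups:
            t0 = _stage(f"identify:{group}")
            real, selections = identify_real_network(
                dataset, network, group, config.strategy, config.exhaustive_cap
            )
            write_real_network(real, out / f"real_gwgen_{group}.tsv")
            write_order_report(selections, out / f"order_report_{group}.jsonl")
            _done(f"identify:{group}", t0, real=summarize_network(real))

            t0 = _stage(f"pnp:{group}")
            core, projection, matrix = pnp(real, config.energy_threshold, config.core_size)
            write_real_network(core, out / f"core_gwgen_{group}.tsv")
            pd.DataFrame({
                "node": matrix.row_index,
                "class": [real.nodes[nid].node_class for nid in matrix.row_index],
                "score": projection.scores,
            }).to_csv(out / f"projection_scores_{group}.tsv", sep="\t", index=False)
            with open(out / f"svd_report_{group}.json", "w") as fh:
                json.dump({
                    "singular_values": projection.singular_values.tolist(),
                    "energies": projection.energies.tolist(),
                    "retained": projection.retained,
                }, fh, indent=1)
            core_edges[group] = {_edge_key(e) for e in core.edges}
            core_nodes[group] = set(core.nodes)
            _done(f"pnp:{group}", t0, core=summarize_network(core),
                  retained=projection.retained)

        if len(config.groups) == 2:
            g1, g2 = config.groups
            t0 = _stage("compare")
            diff = {
                f"edges_only_{g1}": sorted(core_edges[g1] - core_edges[g2]),
                f"edges_only_{g2}": sorted(core_edges[g2] - core_edges[g1]),
                f"nodes_only_{g1}": sorted(core_nodes[g1] - core_nodes[g2]),
                f"nodes_only_{g2}": sorted(core_nodes[g2] - core_nodes[g1]),
            }
            with open(out / "core_comparison.json", "w") as fh:
                json.dump(diff, fh, indent=1)
            _done("compare", t0, **{k: len(v) for k, v in diff.items()})
    except Exception as exc:
        failed = next(
            (n for n, s in manifest["stages"].items() if "elapsed_s" not in s), "unknown"
        )
        manifest["failed_stage"] = failed
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: artifacts in %s", out)
    return manifest
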