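"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

The expression generator draws data *exactly* from the per-node model
equations the identification stage fits.  Driver nodes (TFs, driver lncRNAs
and miRNAs, root proteins) are drawn uniform(0.5, 1.5) per sample; dependent
values solve their model equation in closed form:

    protein   p_q = (lambda + mu) / (1 - sum_r kappa_qr p_r)
    gene      g_x = (sum alpha t + sum beta l + lambda + mu) / (1 + sum gamma m)

(and analogously for lncRNA/miRNA targets), with i.i.d. Gaussian noise mu of
the configured sd.  Dependence is acyclic by construction (regulators are
drawn from upstream tiers) and protein interaction abilities are rescaled so
|sum kappa p_r| <= 0.9 over all samples, keeping the closed form well-posed.
Every generator returns its ground truth alongside the data so downstream
tests never re-derive it.

The remaining generators produce decoy-augmented candidate networks (for
scoring AIC pruning), linearly separable drug-target descriptor data with a
recorded hidden labelling rule, and drug-profile tables with a planted
minimal covering combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .drug_filter import BiomarkerSpec, DrugProfile
from .dti import DTIFeatureSet
from .network import CandidateGWGEN, ExpressionDataset, NodeRecord
from .order_detection import RealGWGEN, WeightedEdge

logger = logging.getLogger("gwgen")

STABILITY_LIMIT = 0.9  # max |sum kappa p_r| for the protein closed form
DENOMINATOR_GUARD = 0.1


@dataclass
class GeneratorConfig:
    """Study conditions for every synthetic fixture; one seed drives all draws."""

    n_tf: int = 6
    n_protein: int = 24
    n_gene: int = 20
    n_lncrna: int = 6
    n_mirna: int = 6
    ppi_partners: int = 2  # candidate interactors per non-root protein
    gene_tf_regs: int = 2
    gene_other_regs: int = 1  # lncRNA/miRNA regulators per target (each)
    ability_range: tuple[float, float] = (0.2, 0.8)
    # basal levels on a log-intensity scale that dominates the regulatory
    # modulation: interaction/regulation effects are perturbations around a
    # substantial baseline, as on microarray log-intensity data
    basal_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.1
    n_samples: int = 200  # per phenotype group
    decoy_fraction: float = 1.0
    group_perturbation: float = 0.25  # fraction of edges re-drawn in the case group
    # DTI block
    n_drugs: int = 200
    n_targets: int = 120
    n_drug_features: int = 363
    n_target_features: int = 996
    n_pairs: int = 2000
    margin: float = 1.0
    label_noise: float = 0.02
    imbalance_ratio: float = 1.0  # negatives per positive
    seed: int = 0


@dataclass
class GroundTruth:
    """A generated real GWGEN with its abilities, basal levels and tiering."""

    network: RealGWGEN
    basal: dict[str, float]
    drivers: list[str]  # nodes drawn uniformly (no incoming edges)
    dependents: list[str]  # nodes solved from their model equation, topological order

    def edge_abilities(self) -> dict[tuple[str, str], float]:
        return {(e.source, e.target): e.ability for e in self.network.edges}


def _signed_ability(rng: np.random.Generator, lo: float, hi: float, sign: int | None) -> float:
    mag = rng.uniform(lo, hi)
    if sign is None:
        sign = -1 if rng.random() < 0.5 else 1
    return sign * mag


def generate_gwgen(config: GeneratorConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Sparse typed ground-truth network with known abilities.

    Tiers (all edges point downstream, so dependence is acyclic):
    TFs, driver lncRNAs/miRNAs and root proteins are sources; dependent
    proteins interact with upstream proteins; dependent lncRNAs/miRNAs and
    all genes are regulated by TFs and driver lncRNAs/miRNAs.  miRNA
    regulation abilities are always negative.
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.ability_range
    nodes: dict[str, NodeRecord] = {}
    edges: list[WeightedEdge] = []
    basal: dict[str, float] = {}

    def _add(nid: str, cls: str) -> str:
        nodes[nid] = NodeRecord(id=nid, symbol=nid.upper(), node_class=cls)
        return nid

    tfs = [_add(f"tf{i:02d}", "TF") for i in range(config.n_tf)]
    proteins = [_add(f"p{i:03d}", "protein") for i in range(config.n_protein)]
    genes = [_add(f"g{i:03d}", "gene") for i in range(config.n_gene)]
    lncs = [_add(f"l{i:02d}", "lncRNA") for i in range(config.n_lncrna)]
    mirs = [_add(f"m{i:02d}", "miRNA") for i in range(config.n_mirna)]

    n_root = max(1, config.n_protein // 3)
    root_proteins, dep_proteins = proteins[:n_root], proteins[n_root:]
    n_drv_lnc = max(1, config.n_lncrna // 2) if lncs else 0
    drv_lncs, dep_lncs = lncs[:n_drv_lnc], lncs[n_drv_lnc:]
    n_drv_mir = max(1, config.n_mirna // 2) if mirs else 0
    drv_mirs, dep_mirs = mirs[:n_drv_mir], mirs[n_drv_mir:]

    if config.ppi_partners < 0 or config.gene_tf_regs < 0 or config.gene_other_regs < 0:
        raise ValueError("edge counts must be nonnegative")
    if config.ppi_partners > 0 and not root_proteins:
        raise ValueError("PPI density incompatible with zero root proteins")
    if config.gene_tf_regs > len(tfs):
        raise ValueError(
            f"gene_tf_regs={config.gene_tf_regs} exceeds the {len(tfs)} available TFs"
        )

    # PPI tier: each dependent protein interacts with root (driver) proteins,
    # whose expression support (0.5, 1.5) is known, so the interaction
    # abilities can be rescaled once at generation time to keep the
    # closed-form inversion well-posed for every possible driver draw
    for q in dep_proteins:
        k = min(config.ppi_partners, len(root_proteins))
        if k == 0:
            root_proteins.append(q)
            continue
        partners = rng.choice(len(root_proteins), size=k, replace=False)
        kappas = [_signed_ability(rng, lo, hi, None) for _ in range(k)]
        worst = 1.5 * sum(abs(x) for x in kappas)  # max |sum kappa p_r| over the support
        if worst > STABILITY_LIMIT:
            kappas = [x * STABILITY_LIMIT / worst for x in kappas]
        for r, kappa in zip(sorted(root_proteins[j] for j in partners), kappas):
            edges.append(WeightedEdge(source=r, target=q, kind="protein", ability=kappa))

    # regulation tiers: genes and dependent lncRNAs/miRNAs
    def _regulate(target: str, mir_pool: list[str]) -> None:
        n_tf_regs = min(config.gene_tf_regs, len(tfs))
        if n_tf_regs:
            for u in sorted(rng.choice(tfs, size=n_tf_regs, replace=False)):
                edges.append(WeightedEdge(source=u, target=target, kind="TF",
                                          ability=_signed_ability(rng, lo, hi, None)))
        for pool, kind, sign in ((drv_lncs, "lncRNA", None), (mir_pool, "miRNA", -1)):
            k = min(config.gene_other_regs, len(pool))
            if k:
                for s in sorted(rng.choice(pool, size=k, replace=False)):
                    edges.append(WeightedEdge(source=s, target=target, kind=kind,
                                              ability=_signed_ability(rng, lo, hi, sign)))

    for target in dep_lncs + dep_mirs:
        pool = [m for m in drv_mirs if m != target]
        _regulate(target, pool)
    for target in genes:
        _regulate(target, drv_mirs)

    for nid in nodes:
        basal[nid] = float(rng.uniform(*config.basal_range))

    drivers = tfs + drv_lncs + drv_mirs + root_proteins
    dependents = [p for p in proteins if p not in root_proteins] + dep_lncs + dep_mirs + genes
    truth = GroundTruth(
        network=RealGWGEN(nodes=nodes, edges=edges),
        basal=basal,
        drivers=drivers,
        dependents=dependents,
    )
    logger.info("synthetic GWGEN: %d nodes, %d edges", len(nodes), len(edges))
    return truth


def perturb_abilities(
    truth: GroundTruth, fraction: float, rng: np.random.Generator,
    ability_range: tuple[float, float] = (0.2, 0.8),
) -> GroundTruth:
    """Re-draw a fraction of edge abilities (sign class preserved for miRNAs)."""
    edges = list(truth.network.edges)
    n_perturb = int(round(fraction * len(edges)))
    if n_perturb == 0:
        return truth
    idx = rng.choice(len(edges), size=n_perturb, replace=False)
    lo, hi = ability_range
    for i in idx:
        e = edges[i]
        sign = -1 if e.kind == "miRNA" else (1 if e.ability >= 0 else -1)
        edges[i] = replace(e, ability=_signed_ability(rng, lo, hi, sign))
    return GroundTruth(
        network=RealGWGEN(nodes=truth.network.nodes, edges=edges),
        basal=truth.basal, drivers=truth.drivers, dependents=truth.dependents,
    )


def _incoming(truth: GroundTruth) -> dict[str, list[WeightedEdge]]:
    incoming: dict[str, list[WeightedEdge]] = {}
    for e in truth.network.edges:
        incoming.setdefault(e.target, []).append(e)
    return incoming


def _simulate_group(
    truth: GroundTruth, config: GeneratorConfig, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    incoming = _incoming(truth)
    nodes = truth.network.nodes
    expr: dict[str, np.ndarray] = {}

    for nid in truth.drivers:
        expr[nid] = rng.uniform(0.5, 1.5, size=n)

    for nid in truth.dependents:
        edges_in = incoming.get(nid, [])
        noise = rng.normal(0.0, config.noise_sd, size=n)
        lam = truth.basal[nid]
        if nodes[nid].is_protein_like:
            coupling = np.zeros(n)
            for e in edges_in:
                coupling += e.ability * expr[e.source]
            denom = 1.0 - coupling
            if np.any(np.abs(denom) < DENOMINATOR_GUARD - 1e-9):
                # cannot happen when the generator's stability rescale holds
                raise ValueError(
                    f"{nid}: interaction denominator within {DENOMINATOR_GUARD} of zero"
                )
            expr[nid] = (lam + noise) / denom
        else:
            numer = lam + noise
            denom = np.ones(n)
            for e in edges_in:
                if e.kind == "miRNA":
                    denom += (-e.ability) * expr[e.source]  # ability < 0
                else:
                    numer += e.ability * expr[e.source]
            if np.any(np.abs(denom) < DENOMINATOR_GUARD):
                raise ValueError(f"{nid}: regulation denominator near zero")
            expr[nid] = numer / denom

    order = sorted(expr)
    return pd.DataFrame({nid: expr[nid] for nid in order}).T


def simulate_expression(
    truth: GroundTruth,
    config: GeneratorConfig,
    case_truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionDataset:
    """Two-group expression drawn exactly from the model equations.

    The control group uses ``truth``; the case group uses ``case_truth`` when
    given (e.g. from :func:`perturb_abilities`) and ``truth`` otherwise.
    ``config.n_samples`` samples per group, noise sd ``config.noise_sd``.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_samples
    control = _simulate_group(truth, config, rng, n)
    case = _simulate_group(case_truth or truth, config, rng, n)
    control.columns = [f"ctrl{j:04d}" for j in range(n)]
    case.columns = [f"case{j:04d}" for j in range(n)]
    expr = pd.concat([control, case], axis=1)
    labels = pd.Series(
        ["control"] * n + ["case"] * n, index=list(control.columns) + list(case.columns)
    )
    return ExpressionDataset(expr, labels)


def add_decoy_edges(
    truth: GroundTruth, fraction: float, seed: int
) -> tuple[CandidateGWGEN, list[tuple[str, str, str]]]:
    """Binary candidate network: every true edge plus typing-consistent decoys.

    Decoys are sampled uniformly (seeded) from the non-edges that respect the
    class typing the true network uses (PPI among upstream proteins,
    regulations from TFs/driver lncRNAs/driver miRNAs onto dependent
    targets), so pruning cannot reject them on type alone.  Returns the
    candidate network and the decoy list ``(source, target, kind)``.
    """
    if fraction < 0:
        raise ValueError("decoy fraction must be >= 0")
    rng = np.random.default_rng(seed)
    cand = CandidateGWGEN(nodes=dict(truth.network.nodes))
    true_ppi = truth.network.undirected_ppi_pairs()
    true_reg = truth.network.directed_regulations()
    for a, b in sorted(true_ppi):
        cand.add_ppi_edge(a, b)
    for s, t in sorted(true_reg):
        cand.add_reg_edge(s, t)

    n_decoys = int(round(fraction * len(truth.network.edges)))
    driver_set = set(truth.drivers)
    nodes = truth.network.nodes
    proteins = sorted(n for n, r in nodes.items() if r.is_protein_like and r.node_class != "TF")
    tfs = sorted(n for n, r in nodes.items() if r.node_class == "TF")
    drv_lncs = sorted(n for n in driver_set if nodes[n].node_class == "lncRNA")
    drv_mirs = sorted(n for n in driver_set if nodes[n].node_class == "miRNA")
    targets = sorted(n for n, r in nodes.items() if r.node_class in {"gene", "lncRNA", "miRNA"}
                     and n not in driver_set)

    pool: list[tuple[str, str, str]] = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            if (min(a, b), max(a, b)) not in true_ppi:
                pool.append((a, b, "protein"))
    for t in targets:
        for s in tfs + drv_lncs + drv_mirs:
            if s != t and (s, t) not in true_reg:
                pool.append((s, t, nodes[s].node_class if nodes[s].node_class != "TF" else "TF"))
    if n_decoys > len(pool):
        raise ValueError(f"not enough non-edges for {n_decoys} decoys (pool {len(pool)})")
    idx = rng.choice(len(pool), size=n_decoys, replace=False)
    decoys = [pool[i] for i in sorted(idx)]
    for s, t, kind in decoys:
        if kind == "protein":
            cand.add_ppi_edge(s, t)
        else:
            cand.add_reg_edge(s, t)
    return cand, decoys


# -- DTI data -------------------------------------------------------------------


@dataclass
class HiddenRule:
    """The linear labelling rule behind a synthetic DTI data set."""

    weights: np.ndarray  # unit vector over the concatenated descriptor space
    margin: float

    def score(self, x: np.ndarray) -> float:
        return float(self.weights @ x)

    def label(self, x: np.ndarray) -> int:
        return int(self.score(x) > 0)


def generate_dti_data(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[DTIFeatureSet, HiddenRule, np.ndarray]:
    """Gaussian descriptors with labels from a hidden linear margin rule.

    Pair labels are the sign of a unit-norm linear score of the concatenated
    [drug, target] vector; pairs scoring within the margin of zero are
    discarded, labels are flipped at the label-noise rate, and the
    negative:positive imbalance ratio is enforced.  Returns the feature set,
    the hidden rule, and the pre-noise labels.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    md, mt = config.n_drug_features, config.n_target_features
    drugs = pd.DataFrame(
        rng.normal(size=(config.n_drugs, md)),
        index=[f"drug{i:04d}" for i in range(config.n_drugs)],
        columns=[f"d{i}" for i in range(md)],
    )
    targets = pd.DataFrame(
        rng.normal(size=(config.n_targets, mt)),
        index=[f"target{i:04d}" for i in range(config.n_targets)],
        columns=[f"t{i}" for i in range(mt)],
    )
    w = rng.normal(size=md + mt)
    w /= np.linalg.norm(w)
    rule = HiddenRule(weights=w, margin=config.margin)

    n_pos_goal = int(round(config.n_pairs / (1.0 + config.imbalance_ratio)))
    n_neg_goal = config.n_pairs - n_pos_goal
    combos = [(d, t) for d in drugs.index for t in targets.index]
    rng.shuffle(combos)
    rows, clean = [], []
    n_pos = n_neg = 0
    for d, t in combos:
        if n_pos >= n_pos_goal and n_neg >= n_neg_goal:
            break
        x = np.concatenate([drugs.loc[d].to_numpy(), targets.loc[t].to_numpy()])
        s = rule.score(x)
        if abs(s) < config.margin:
            continue
        lab = int(s > 0)
        if lab == 1 and n_pos < n_pos_goal:
            n_pos += 1
        elif lab == 0 and n_neg < n_neg_goal:
            n_neg += 1
        else:
            continue
        rows.append((d, t, lab))
        clean.append(lab)
    if n_pos < n_pos_goal or n_neg < n_neg_goal:
        raise ValueError(
            f"could only draw {n_pos}+{n_neg} of {n_pos_goal}+{n_neg_goal} pairs;"
            " increase n_drugs/n_targets or lower the margin"
        )
    pairs = pd.DataFrame(rows, columns=["drug", "target", "label"])
    clean_labels = np.array(clean)
    flips = rng.random(len(pairs)) < config.label_noise
    pairs.loc[flips, "label"] = 1 - pairs.loc[flips, "label"]
    return DTIFeatureSet(drug_features=drugs, target_features=targets, pairs=pairs), rule, clean_labels


# -- drug profiles --------------------------------------------------------------


def generate_drug_profiles(
    biomarkers: list[BiomarkerSpec],
    n_drugs: int,
    seed: int,
    plant_size: int | None = None,
) -> tuple[list[DrugProfile], list[str]]:
    """Profiles with a planted minimal covering set among distractors.

    Planted drugs jointly cover all biomarkers sign-consistently with large
    |regulation| (0.5..1.0); distractors are sign-consistent on at most one
    biomarker with small |regulation| (< 0.3), so the plant is the unique
    minimal cover.  Returns ``(profiles, planted drug names)``.
    """
    if not biomarkers:
        raise ValueError("need at least one biomarker")
    rng = np.random.default_rng(seed)
    k = plant_size if plant_size is not None else max(1, (len(biomarkers) + 1) // 2)
    k = min(k, len(biomarkers))
    assignment = [[] for _ in range(k)]
    for i, marker in enumerate(biomarkers):
        assignment[i % k].append(marker)
    # give each planted drug a second marker where possible so covers overlap
    profiles: list[DrugProfile] = []
    planted = []

    def _reversing(direction: str) -> float:
        mag = rng.uniform(0.5, 1.0)
        return mag if direction == "-" else -mag

    def _nonreversing(direction: str) -> float:
        mag = rng.uniform(0.0, 0.3)
        return -mag if direction == "-" else mag

    for i, markers in enumerate(assignment):
        name = f"plant{i:02d}"
        planted.append(name)
        reg = {m.name: _reversing(m.direction) for m in markers}
        profiles.append(DrugProfile(
            name=name, regulation=reg,
            sensitivity=float(rng.uniform(-0.8, 0.0)),
            toxicity=float(rng.uniform(2.0, 5.5)),
        ))
    for i in range(max(0, n_drugs - k)):
        name = f"decoy{i:03d}"
        reg = {m.name: _nonreversing(m.direction) for m in biomarkers}
        if rng.random() < 0.5:  # half the distractors weakly reverse one marker
            m = biomarkers[int(rng.integers(len(biomarkers)))]
            mag = rng.uniform(0.05, 0.3)
            reg[m.name] = mag if m.direction == "-" else -mag
        profiles.append(DrugProfile(
            name=name, regulation=reg,
            sensitivity=float(rng.uniform(-0.8, 0.7)),
            toxicity=float(rng.uniform(2.0, 5.5)),
        ))
    return profiles, planted
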