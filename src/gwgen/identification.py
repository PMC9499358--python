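"""System identification: per-node constrained least-squares fits.

Each node of the candidate GWGEN obeys a static linear model over the N
expression samples:

* protein q (PPIN):  p_q[n] = sum_r kappa_qr p_q[n] p_r[n] + lambda_q + mu[n]
* gene x (GRN):      g_x[n] = sum_u alpha_xu t_u[n] + sum_v beta_xv l_v[n]
                              - sum_w gamma_xw m_w[n] g_x[n] + lambda_x + mu[n]

and analogous forms for lncRNA and miRNA targets.  The miRNA terms carry a
sign constraint: the fitted coefficient on each m_w[n] * (own expression)
column must be <= 0 (post-transcriptional repression), i.e. gamma, tau, psi
>= 0.  The basal level lambda absorbs unmodelled epigenetic effects and is
the intercept column.  Parameters are estimated by least squares with the
nonpositivity constraints; the residual error Omega = ||y - Phi theta||^2 / N
feeds the AIC order-detection step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .network import CandidateGWGEN, CandidateSets, ExpressionDataset, candidate_sets

logger = logging.getLogger("gwgen")

BASAL = "<basal>"
SOLVER_TOL = 1e-9


@dataclass
class RegressionProblem:
    """One node's regression: response y, design Phi, and the sign-constraint mask.

    The final design column is the intercept (basal level).  The constraint
    mask is True exactly on miRNA-regressor columns, whose coefficients are
    constrained <= 0.
    """

    node_id: str
    node_class: str
    response: np.ndarray
    design: np.ndarray
    constraint_mask: np.ndarray
    column_labels: list[tuple[str, str]]  # (regulator id, kind); last is (BASAL, "basal")

    def __post_init__(self) -> None:
        n, k = self.design.shape
        if self.response.shape != (n,):
            raise ValueError("response/design row mismatch")
        if self.constraint_mask.shape != (k,) or len(self.column_labels) != k:
            raise ValueError("constraint mask / labels do not match design columns")

    @property
    def order(self) -> int:
        """Number of interaction/regulation regressors (excludes the intercept)."""
        return self.design.shape[1] - 1


@dataclass
class NodeModel:
    """Fitted parameters of one node's model."""

    node_id: str
    node_class: str
    coefficients: dict[str, float]  # regulator id -> ability estimate
    coefficient_kinds: dict[str, str]  # regulator id -> regressor kind
    basal: float
    residual_error: float  # Omega = SSR / N
    n_samples: int
    rank_deficient: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def regulators(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_record(self) -> dict:
        return {
            "node": self.node_id,
            "class": self.node_class,
            "coefficients": self.coefficients,
            "kinds": self.coefficient_kinds,
            "basal": self.basal,
            "residual_error": self.residual_error,
            "n_samples": self.n_samples,
            "warnings": self.warnings + (["rank_deficient"] if self.rank_deficient else []),
        }


def build_protein_regression(
    dataset: ExpressionDataset,
    node_id: str,
    interactors: list[str] | tuple[str, ...],
    group: str | None = None,
    node_class: str = "protein",
) -> RegressionProblem:
    """Design matrix of the protein interaction model.

    Column r holds the productwise regressor p_q[n] * p_r[n]; the intercept
    column (basal level) is last.  No columns are sign-constrained.
    """
    y = dataset.values(node_id, group)
    cols = [dataset.values(r, group) * y for r in interactors]
    cols.append(np.ones_like(y))
    design = np.column_stack(cols)
    labels = [(r, "protein") for r in interactors] + [(BASAL, "basal")]
    return RegressionProblem(
        node_id=node_id,
        node_class=node_class,
        response=y,
        design=design,
        constraint_mask=np.zeros(design.shape[1], dtype=bool),
        column_labels=labels,
    )


def build_regulation_regression(
    dataset: ExpressionDataset,
    node_id: str,
    node_class: str,
    tf_set: list[str] | tuple[str, ...],
    lnc_set: list[str] | tuple[str, ...],
    mir_set: list[str] | tuple[str, ...],
    group: str | None = None,
) -> RegressionProblem:
    """Design matrix of the regulation model for a gene/lncRNA/miRNA target.

    TF columns carry t_u[n], lncRNA columns l_v[n]; each miRNA column carries
    m_w[n] multiplied by the target's own expression and is sign-constrained
    (coefficient <= 0).  Intercept last.
    """
    if node_class not in {"gene", "lncRNA", "miRNA"}:
        raise ValueError(f"{node_id!r}: regulation model needs a target class, got {node_class!r}")
    y = dataset.values(node_id, group)
    cols, labels = [], []
    for u in tf_set:
        cols.append(dataset.values(u, group))
        labels.append((u, "TF"))
    for v in lnc_set:
        cols.append(dataset.values(v, group))
        labels.append((v, "lncRNA"))
    for w in mir_set:
        cols.append(dataset.values(w, group) * y)
        labels.append((w, "miRNA"))
    cols.append(np.ones_like(y))
    labels.append((BASAL, "basal"))
    design = np.column_stack(cols)
    mask = np.array([kind == "miRNA" for _, kind in labels])
    return RegressionProblem(
        node_id=node_id,
        node_class=node_class,
        response=y,
        design=design,
        constraint_mask=mask,
        column_labels=labels,
    )


def solve_constrained_lsq(
    problem: RegressionProblem,
) -> tuple[np.ndarray, float, bool]:
    """Minimize (1/2)||Phi theta - y||^2 s.t. masked coefficients <= 0.

    Returns ``(theta_hat, residual_error, rank_deficient)`` with
    residual_error = ||y - Phi theta_hat||^2 / N (division by N, not by the
    residual degrees of freedom).  When the unconstrained least-squares
    optimum already satisfies the constraints it is returned directly
    (minimum-norm solution on rank-deficient designs); otherwise a
    bound-constrained solver refines it.
    """
    phi, y, mask = problem.design, problem.response, problem.constraint_mask
    n, k = phi.shape
    theta, _, rank, _ = np.linalg.lstsq(phi, y, rcond=None)
    rank_deficient = rank < k
    if mask.any() and np.any(theta[mask] > SOLVER_TOL):
        ub = np.where(mask, 0.0, np.inf)
        res = lsq_linear(phi, y, bounds=(-np.inf, ub), tol=1e-12, method="bvls" if rank == k and n >= k else "trf")
        theta = res.x
    theta = theta.copy()
    theta[mask] = np.minimum(theta[mask], 0.0)  # clip solver slack within tolerance
    resid = y - phi @ theta
    omega = float(resid @ resid) / n
    if rank_deficient:
        logger.warning("%s: rank-deficient design (rank %d < %d columns)", problem.node_id, rank, k)
    return theta, omega, rank_deficient


def build_problem(
    dataset: ExpressionDataset,
    network: CandidateGWGEN,
    node_id: str,
    regulator_subset: tuple[str, ...] | list[str] | None = None,
    group: str | None = None,
    sets: CandidateSets | None = None,
) -> RegressionProblem:
    """Build a node's regression problem, optionally restricted to a regulator subset."""
    cand = sets if sets is not None else candidate_sets(network, node_id)
    if regulator_subset is not None:
        keep = set(regulator_subset)
        extra = keep - set(cand.interactors) - set(cand.all_regulators)
        if extra:
            raise ValueError(f"{node_id!r}: regulators outside candidate sets: {sorted(extra)}")
    else:
        keep = None

    def _sel(ids: tuple[str, ...]) -> list[str]:
        return [i for i in ids if keep is None or i in keep]

    rec = network.node(node_id)
    if rec.is_protein_like:
        return build_protein_regression(
            dataset, node_id, _sel(cand.interactors), group, node_class=rec.node_class
        )
    return build_regulation_regression(
        dataset, node_id, rec.node_class,
        _sel(cand.tfs), _sel(cand.lncrnas), _sel(cand.mirnas), group,
    )


def fit_problem(problem: RegressionProblem) -> NodeModel:
    theta, omega, rank_def = solve_constrained_lsq(problem)
    coeffs, kinds = {}, {}
    basal = 0.0
    for (rid, kind), value in zip(problem.column_labels, theta):
        if rid == BASAL:
            basal = float(value)
        else:
            coeffs[rid] = float(value)
            kinds[rid] = kind
    return NodeModel(
        node_id=problem.node_id,
        node_class=problem.node_class,
        coefficients=coeffs,
        coefficient_kinds=kinds,
        basal=basal,
        residual_error=omega,
        n_samples=len(problem.response),
        rank_deficient=rank_def,
    )


def fit_node(
    dataset: ExpressionDataset,
    network: CandidateGWGEN,
    node_id: str,
    regulator_subset: tuple[str, ...] | list[str] | None = None,
    group: str | None = None,
) -> NodeModel:
    """Fit one node's interaction/regulation model on the samples of a group."""
    return fit_problem(build_problem(dataset, network, node_id, regulator_subset, group))
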