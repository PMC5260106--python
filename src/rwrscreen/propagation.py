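"""Two restarting random walks from effective/ineffective seeds, F-ratio scoring.

Starting from a column-normalized two-column seed matrix ``L'`` the iteration

    P(t+1) = (1 - alpha) * T @ P(t) + alpha * L',    P(0) = L'

is run to convergence (summed L1 change below ``epsilon``).  Column 0 holds
the walk restarted at ineffective seeds, column 1 the walk restarted at
effective seeds (drugs plus optional phenotype-gene proteins).  Each node is
scored by the odds ``F(i) = P*(i, 1) / P*(i, 0)``; nodes above a threshold
``theta`` are called effective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, FormatError, ValidationError
from .network import BipartiteNetwork, TransitionMatrix

__all__ = [
    "LabelSet",
    "LabelMatrix",
    "PropagationResult",
    "read_labels",
    "write_labels",
    "build_label_matrix",
    "propagate",
    "solve_stationary_direct",
    "f_ratio",
    "classify",
    "rank",
    "screen",
]

#: guard for the dense closed-form solver
_DENSE_SOLVE_LIMIT = 2000


@dataclass(frozen=True)
class LabelSet:
    """Seed drugs (and optional phenotype-associated genes) for the two walks."""

    effective_drugs: frozenset[str]
    ineffective_drugs: frozenset[str]
    aging_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "effective_drugs", frozenset(self.effective_drugs))
        object.__setattr__(self, "ineffective_drugs", frozenset(self.ineffective_drugs))
        object.__setattr__(self, "aging_genes", frozenset(self.aging_genes))
        overlap = self.effective_drugs & self.ineffective_drugs
        if overlap:
            raise ValidationError(
                f"drugs labeled both effective and ineffective: {sorted(overlap)[:5]}"
            )

    def validate_against(self, net: BipartiteNetwork) -> None:
        drugs = set(net.drug_ids)
        proteins = set(net.protein_ids)
        for name, ids, universe in (
            ("effective drug", self.effective_drugs, drugs),
            ("ineffective drug", self.ineffective_drugs, drugs),
            ("aging gene", self.aging_genes, proteins),
        ):
            missing = ids - universe
            if missing:
                raise ValidationError(
                    f"{name} seed(s) absent from network: {sorted(missing)[:5]}"
                )
        if not (self.effective_drugs | self.aging_genes):
            raise ValidationError("effective side has no seeds")
        if not self.ineffective_drugs:
            raise ValidationError("ineffective side has no seeds")


@dataclass
class LabelMatrix:
    """|V| x 2 indicator matrix and its column-normalized counterpart."""

    L: np.ndarray
    L_norm: np.ndarray

    def __post_init__(self) -> None:
        if self.L.shape != self.L_norm.shape or self.L.shape[1] != 2:
            raise ValidationError("label matrices must both be |V| x 2")
        if not np.isin(self.L, (0.0, 1.0)).all():
            raise ValidationError("label matrix entries must be 0 or 1")
        colsums = self.L_norm.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-12:
            raise ValidationError("normalized label columns must each sum to 1")


@dataclass
class PropagationResult:
    """Stationary matrix, per-node odds, and convergence diagnostics."""

    P_star: np.ndarray
    f_ratio: np.ndarray
    iterations: int
    residual: float
    alpha: float
    pseudocount: float = 0.0


def read_labels(path: str | Path) -> LabelSet:
    """Read a labels TSV with columns ``id`` and ``class``.

    ``class`` must be one of ``effective``, ``ineffective``, ``aging_gene``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("id", "class") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    groups: dict[str, set[str]] = {"effective": set(), "ineffective": set(), "aging_gene": set()}
    for node_id, cls in zip(df["id"].astype(str), df["class"].astype(str)):
        if cls not in groups:
            raise FormatError(f"{path}: unknown class {cls!r} for id {node_id!r}")
        groups[cls].add(node_id)
    return LabelSet(
        effective_drugs=frozenset(groups["effective"]),
        ineffective_drugs=frozenset(groups["ineffective"]),
        aging_genes=frozenset(groups["aging_gene"]),
    )


def write_labels(labels: LabelSet, path: str | Path) -> None:
    lines = ["id\tclass"]
    for cls, ids in (
        ("effective", labels.effective_drugs),
        ("ineffective", labels.ineffective_drugs),
        ("aging_gene", labels.aging_genes),
    ):
        lines.extend(f"{i}\t{cls}" for i in sorted(ids))
    Path(path).write_text("\n".join(lines) + "\n")


def build_label_matrix(net: BipartiteNetwork, labels: LabelSet) -> LabelMatrix:
    """Build the |V| x 2 seed-indicator matrix and normalize each column.

    Column 0 marks ineffective drugs; column 1 marks effective drugs and any
    phenotype-gene proteins.  Each column of ``L_norm`` is a probability
    distribution over the seeds of that class.
    """
    labels.validate_against(net)
    L = np.zeros((net.n_nodes, 2))
    for d in labels.ineffective_drugs:
        L[net.index_of(d), 0] = 1.0
    for d in labels.effective_drugs:
        L[net.index_of(d), 1] = 1.0
    for g in labels.aging_genes:
        L[net.index_of(g), 1] = 1.0
    return LabelMatrix(L=L, L_norm=L / L.sum(axis=0))


def propagate(
    T: TransitionMatrix,
    L: LabelMatrix,
    alpha: float = 0.5,
    epsilon: float = 1e-9,
    max_iter: int = 10_000,
) -> PropagationResult:
    """Iterate the restarting walk to its stationary matrix.

    Raises :class:`ConvergenceError` (carrying the last residual) if the
    summed L1 change has not dropped below ``epsilon`` within ``max_iter``
    steps; convergence is never silent-failed.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must be in (0, 1]")
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    if T.n_nodes != L.L.shape[0]:
        raise ValidationError("transition and label matrices disagree on |V|")

    M = T.matrix
    restart = alpha * L.L_norm
    P = L.L_norm.copy()
    for it in range(1, max_iter + 1):
        P_next = (1.0 - alpha) * (M @ P) + restart
        residual = float(np.abs(P_next - P).sum())
        P = P_next
        if residual < epsilon:
            return PropagationResult(
                P_star=P,
                f_ratio=f_ratio(P),
                iterations=it,
                residual=residual,
                alpha=alpha,
            )
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (residual {residual:.3e})",
        iterations=max_iter,
        residual=residual,
    )


def solve_stationary_direct(
    T: TransitionMatrix, L: LabelMatrix, alpha: float = 0.5
) -> np.ndarray:
    """Closed-form stationary solution ``alpha (I - (1-alpha) T)^-1 L'``.

    Dense linear solve, guarded to small networks; serves as the independent
    oracle for :func:`propagate`.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must be in (0, 1]")
    n = T.n_nodes
    if n > _DENSE_SOLVE_LIMIT:
        raise ValidationError(f"direct solve guarded to |V| <= {_DENSE_SOLVE_LIMIT}")
    system = np.eye(n) - (1.0 - alpha) * T.matrix.toarray()
    # spectral radius of (1-alpha)T is < 1 for alpha > 0, so system is regular
    return alpha * np.linalg.solve(system, L.L_norm)


def f_ratio(P_star: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Per-node odds of the effective walk over the ineffective walk.

    With ``pseudocount == 0`` the division policy is: 0/0 -> 0 and
    x/0 -> +inf for x > 0.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if P_star.min() < 0:
        raise ValidationError("stationary matrix must be nonnegative")
    num = P_star[:, 1] + pseudocount
    den = P_star[:, 0] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / den
    F[(num == 0) & (den == 0)] = 0.0
    return F


def classify(F: np.ndarray, theta: float) -> np.ndarray:
    """Boolean effective-call vector: strictly ``F > theta``."""
    if theta <= 0:
        raise ValidationError("theta must be > 0")
    return F > theta


def rank(F: np.ndarray, node_ids: Sequence[str]) -> list[str]:
    """Node ids in descending F order; ties broken lexicographically by id."""
    if len(F) != len(node_ids):
        raise ValidationError("F vector and node id list disagree in length")
    return [node_ids[i] for i in sorted(range(len(F)), key=lambda i: (-F[i], node_ids[i]))]


def screen(
    net: BipartiteNetwork,
    labels: LabelSet,
    alpha: float = 0.5,
    epsilon: float = 1e-9,
    max_iter: int = 10_000,
    theta: float = 2.0,
    pseudocount: float = 0.0,
) -> tuple[pd.DataFrame, PropagationResult]:
    """Full pipeline on one network: label matrix, walk, odds, ranking.

    Returns a ranked table (node_id, node_type, P_neg, P_pos, F_ratio, rank,
    call) plus the raw propagation result.
    """
    from .network import transition_matrix  # local import avoids cycle at module load

    T = transition_matrix(net)
    L = build_label_matrix(net, labels)
    result = propagate(T, L, alpha=alpha, epsilon=epsilon, max_iter=max_iter)
    F = f_ratio(result.P_star, pseudocount=pseudocount)
    result.f_ratio = F
    result.pseudocount = pseudocount
    node_ids = net.node_ids
    order = rank(F, node_ids)
    rank_of = {nid: r + 1 for r, nid in enumerate(order)}
    calls = classify(F, theta)
    df = pd.DataFrame(
        {
            "node_id": node_ids,
            "node_type": ["drug"] * net.n_drugs + ["protein"] * net.n_proteins,
            "P_neg": result.P_star[:, 0],
            "P_pos": result.P_star[:, 1],
            "F_ratio": F,
            "rank": [rank_of[nid] for nid in node_ids],
            "call": np.where(calls, "effective", "ineffective"),
        }
    )
    return df.sort_values("rank", kind="stable").reset_index(drop=True), result
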