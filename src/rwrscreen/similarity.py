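"""Drug-drug similarity measures: chemical cosine, target Jaccard, noisy-OR.

Chemical similarity is the raw cosine of attribute vectors (may be negative
for descriptor-bearing vectors); target similarity is the Jaccard score of
target-protein sets; the integrated measure combines channels as
``1 - prod(1 - S_n)`` after flooring negatives at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .network import BipartiteNetwork

__all__ = [
    "ChemicalProfile",
    "TargetProfile",
    "SimilarityMatrix",
    "read_attributes",
    "write_attributes",
    "read_similarity",
    "write_similarity",
    "remove_constant_attributes",
    "cosine_similarity",
    "target_jaccard",
    "target_profiles_from_network",
    "integrate_similarities",
    "to_distance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChemicalProfile:
    """One drug's numeric attribute vector (descriptors + fingerprint bits)."""

    drug_id: str
    attributes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "attributes", np.asarray(self.attributes, dtype=float)
        )
        if self.attributes.ndim != 1:
            raise ValidationError("attributes must be a 1-D vector")


@dataclass(frozen=True)
class TargetProfile:
    """One drug's binary membership vector over the protein universe."""

    drug_id: str
    targets: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.targets, dtype=float)
        if not np.isin(t, (0.0, 1.0)).all():
            raise ValidationError(f"non-binary target profile for {self.drug_id}")
        object.__setattr__(self, "targets", t.astype(np.int8))

    @property
    def target_set(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.targets).tolist())


@dataclass
class SimilarityMatrix:
    """Symmetric drug-drug similarity with a provenance tag."""

    ids: list[str]
    S: np.ndarray
    kind: str  # chemical | target | integrated

    def __post_init__(self) -> None:
        if self.kind not in ("chemical", "target", "integrated"):
            raise ValidationError(f"unknown similarity kind {self.kind!r}")
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("similarity matrix shape does not match ids")
        if np.abs(self.S - self.S.T).max() > 0:
            raise ValidationError("similarity matrix is not symmetric")
        lo = -1.0 if self.kind == "chemical" else 0.0
        if self.S.size and (self.S.min() < lo - 1e-12 or self.S.max() > 1 + 1e-12):
            raise ValidationError(f"{self.kind} similarities outside [{lo}, 1]")

    def index_of(self, drug_id: str) -> int:
        return self.ids.index(drug_id)


# ---------------------------------------------------------------------------
# I/O


def read_attributes(path: str | Path) -> list[ChemicalProfile]:
    """Read an attribute CSV: first column ``drug_id``, rest numeric."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a drug_id column plus attributes")
    ids = df.iloc[:, 0].astype(str)
    try:
        X = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric attribute value ({exc})") from None
    return [ChemicalProfile(i, row) for i, row in zip(ids, X)]


def write_attributes(profiles: Sequence[ChemicalProfile], path: str | Path) -> None:
    k = len(profiles[0].attributes)
    df = pd.DataFrame(
        [p.attributes for p in profiles],
        index=pd.Index([p.drug_id for p in profiles], name="drug_id"),
        columns=[f"attr_{j}" for j in range(k)],
    )
    df.to_csv(path)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids).to_csv(path)


def read_similarity(path: str | Path, kind: str = "integrated") -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column drug ids disagree")
    return SimilarityMatrix(ids=ids, S=df.to_numpy(dtype=float), kind=kind)


# ---------------------------------------------------------------------------
# operations


def remove_constant_attributes(
    profiles: Sequence[ChemicalProfile],
) -> list[ChemicalProfile]:
    """Drop attribute columns whose value is identical across all drugs."""
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles to detect constants")
    X = np.vstack([p.attributes for p in profiles])
    keep = ~np.all(X == X[0, :], axis=0)
    if not keep.any():
        raise ValidationError("all attributes are constant; nothing informative")
    return [ChemicalProfile(p.drug_id, X[i, keep]) for i, p in enumerate(profiles)]


def cosine_similarity(profiles: Sequence[ChemicalProfile]) -> SimilarityMatrix:
    """Pairwise cosine of attribute vectors (kind=chemical, range [-1, 1]).

    Drugs with an all-zero attribute vector get similarity 0 to everything
    (logged as a warning); their diagonal entry is 0, not 1.
    """
    ids = [p.drug_id for p in profiles]
    X = np.vstack([p.attributes for p in profiles])
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning(
            "zero-norm attribute vector(s) for %s; similarities set to 0",
            [ids[i] for i in np.flatnonzero(zero)[:5]],
        )
    safe = np.where(zero, 1.0, norms)
    S = (X / safe[:, None]) @ (X / safe[:, None]).T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, np.where(zero, 0.0, 1.0))
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(ids=ids, S=S, kind="chemical")


def target_jaccard(profiles: Sequence[TargetProfile]) -> SimilarityMatrix:
    """Shared-target ratio |t_i & t_j| / |t_i | t_j| (kind=target).

    A pair with both profiles empty scores 0; the diagonal is 1 for drugs
    with at least one target.
    """
    ids = [p.drug_id for p in profiles]
    B = np.vstack([p.targets for p in profiles]).astype(float)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, np.where(sizes > 0, 1.0, 0.0))
    return SimilarityMatrix(ids=ids, S=S, kind="target")


def target_profiles_from_network(net: BipartiteNetwork) -> list[TargetProfile]:
    """Read each drug's binary target vector off the network's edges."""
    m = net.n_drugs
    block = (net.A[:m, m:] != 0).toarray()
    return [TargetProfile(d, block[i]) for i, d in enumerate(net.drug_ids)]


def integrate_similarities(
    matrices: Sequence[SimilarityMatrix],
) -> SimilarityMatrix:
    """Noisy-OR combination ``1 - prod(1 - S_n)`` (kind=integrated).

    Negative entries (possible for raw chemical cosine) are floored at 0
    before combination, honoring the [0, 1] contract of the formula.
    """
    if not matrices:
        raise ValidationError("need at least one similarity matrix")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValidationError("similarity matrices disagree on drug ordering")
    prod = np.ones((len(ids), len(ids)))
    for m in matrices:
        prod *= 1.0 - np.clip(m.S, 0.0, 1.0)
    return SimilarityMatrix(ids=list(ids), S=1.0 - prod, kind="integrated")


def to_distance(sim: SimilarityMatrix) -> np.ndarray:
    """Elementwise distance ``1 - S``; requires similarities in [0, 1]."""
    if sim.S.size and (sim.S.min() < 0 or sim.S.max() > 1):
        raise ValidationError(
            "similarities outside [0, 1]; integrate (or clip) before converting"
        )
    D = 1.0 - sim.S
    np.fill_diagonal(D, 0.0)
    return D
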