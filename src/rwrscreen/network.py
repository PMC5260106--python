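"""Weighted drug-protein bipartite network: ingestion, filtering, assembly.

The network is held as a symmetric nonnegative affinity matrix ``A`` over the
joint node set (drugs first, then proteins).  Edges exist only between a drug
and a protein; the row-stochastic transition matrix is ``T = D^-1 A`` with
``D`` the diagonal degree matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import ConstructionError, FormatError, ValidationError

__all__ = [
    "InteractionRecord",
    "OrthologRecord",
    "InteractionDialect",
    "STITCH_DIALECT",
    "BipartiteNetwork",
    "TransitionMatrix",
    "read_interactions",
    "read_orthologs",
    "filter_high_confidence",
    "map_orthologs",
    "build_network",
    "prune_components",
    "transition_matrix",
    "save_network",
    "load_network",
]

#: evidence channels carried by every interaction record, in canonical order
CHANNELS = ("experimental", "database", "textmining", "predicted", "combined")


@dataclass(frozen=True)
class InteractionRecord:
    """One weighted drug-protein edge with per-channel evidence scores.

    All scores live in [0, 1] after dialect normalization.
    """

    drug_id: str
    protein_id: str
    experimental: float = 0.0
    database: float = 0.0
    textmining: float = 0.0
    predicted: float = 0.0
    combined: float = 0.0

    def __post_init__(self) -> None:
        if not self.drug_id or not self.protein_id:
            raise ValidationError("drug_id and protein_id must be non-empty")
        for ch in CHANNELS:
            v = getattr(self, ch)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"score {ch}={v!r} outside [0, 1] for "
                    f"({self.drug_id}, {self.protein_id})"
                )


@dataclass(frozen=True)
class OrthologRecord:
    """Protein-to-protein ortholog mapping supported by ``n_methods`` predictors."""

    source_protein: str
    target_protein: str
    n_methods: int

    def __post_init__(self) -> None:
        if self.n_methods < 1:
            raise ValidationError("n_methods must be >= 1")


@dataclass(frozen=True)
class InteractionDialect:
    """Column naming and score scale of an interaction TSV.

    ``scale`` is the value a raw score is divided by to land in [0, 1]
    (1000 for STITCH-style integer scores, 1 for already-normalized files).
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "drug_id": "chemical",
            "protein_id": "protein",
            "experimental": "experimental",
            "database": "database",
            "textmining": "textmining",
            "predicted": "prediction",
            "combined": "combined_score",
        }
    )
    scale: float = 1000.0

    def __post_init__(self) -> None:
        missing = {"drug_id", "protein_id"} - set(self.columns)
        if missing:
            raise ValidationError(f"dialect misses id columns: {sorted(missing)}")
        if self.scale <= 0:
            raise ValidationError("dialect scale must be > 0")


STITCH_DIALECT = InteractionDialect()


@dataclass
class BipartiteNetwork:
    """Node registries plus symmetric nonnegative affinity matrix.

    ``A`` is (m+n) x (m+n) sparse CSR; row/column order is ``drug_ids``
    followed by ``protein_ids``.
    """

    drug_ids: list[str]
    protein_ids: list[str]
    A: sp.csr_matrix

    def __post_init__(self) -> None:
        m, n = len(self.drug_ids), len(self.protein_ids)
        if self.A.shape != (m + n, m + n):
            raise ValidationError(
                f"affinity matrix shape {self.A.shape} != ({m + n}, {m + n})"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_proteins

    @property
    def node_ids(self) -> list[str]:
        return self.drug_ids + self.protein_ids

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except AttributeError:
            self._index = {nid: i for i, nid in enumerate(self.node_ids)}
            return self._index[node_id]

    def is_drug(self, node_id: str) -> bool:
        return self.index_of(node_id) < self.n_drugs

    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()

    def validate(self) -> None:
        """Assert symmetry, nonnegativity, and bipartiteness of ``A``."""
        if (self.A != self.A.T).nnz != 0:
            raise ValidationError("affinity matrix is not symmetric")
        if self.A.nnz and self.A.data.min() < 0:
            raise ValidationError("affinity matrix has negative entries")
        m = self.n_drugs
        coo = sp.triu(self.A).tocoo()
        drug_drug = (coo.row < m) & (coo.col < m)
        prot_prot = (coo.row >= m) & (coo.col >= m)
        if drug_drug.any() or prot_prot.any():
            raise ValidationError("edge within one partition breaks bipartiteness")


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix ``T = D^-1 A`` over the network nodes."""

    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        rowsums = np.asarray(self.matrix.sum(axis=1)).ravel()
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValidationError("transition matrix has negative entries")
        if np.abs(rowsums - 1.0).max() > 1e-12:
            raise ValidationError("transition matrix rows do not sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# ingestion


def _collapse_duplicates(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse duplicate (drug, protein) records to the per-channel max.

    First-appearance order of the key is preserved.
    """
    merged: dict[tuple[str, str], InteractionRecord] = {}
    for rec in records:
        key = (rec.drug_id, rec.protein_id)
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec
        else:
            merged[key] = InteractionRecord(
                rec.drug_id,
                rec.protein_id,
                **{ch: max(getattr(prev, ch), getattr(rec, ch)) for ch in CHANNELS},
            )
    return list(merged.values())


def read_interactions(
    path: str | Path, dialect: InteractionDialect = STITCH_DIALECT
) -> list[InteractionRecord]:
    """Read an interaction TSV into records with scores rescaled to [0, 1].

    Duplicate (drug, protein) rows are collapsed to the per-channel maximum.
    Channels absent from the dialect's column map default to 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in dialect.columns.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []

    scores: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        col = dialect.columns.get(ch)
        if col is None:
            scores[ch] = np.zeros(len(df))
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise FormatError(
                f"{path}: unparseable score in column {col!r} at line {row + 2}"
            )
        scores[ch] = parsed.to_numpy(dtype=float) / dialect.scale

    records = [
        InteractionRecord(
            str(df[dialect.columns["drug_id"]].iat[i]),
            str(df[dialect.columns["protein_id"]].iat[i]),
            **{ch: float(scores[ch][i]) for ch in CHANNELS},
        )
        for i in range(len(df))
    ]
    return _collapse_duplicates(records)


def read_orthologs(path: str | Path) -> list[OrthologRecord]:
    """Read an ortholog TSV with columns ``source``, ``target``, ``n_methods``."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = [c for c in ("source", "target", "n_methods") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        OrthologRecord(str(r.source), str(r.target), int(r.n_methods))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# filtering and mapping


def filter_high_confidence(
    records: Sequence[InteractionRecord], threshold: float = 0.0
) -> list[InteractionRecord]:
    """Keep records with experimental or curated-database evidence.

    A record passes when ``experimental > threshold`` or
    ``database > threshold`` (default: any strictly positive evidence).
    Order is preserved; text mining or predicted evidence alone never suffices.
    """
    return [
        r for r in records if r.experimental > threshold or r.database > threshold
    ]


def map_orthologs(
    records: Sequence[InteractionRecord],
    orthologs: Sequence[OrthologRecord],
    min_methods: int = 2,
) -> list[InteractionRecord]:
    """Translate protein ids through an ortholog table.

    Each record whose protein has one or more ortholog rows supported by at
    least ``min_methods`` prediction methods is replaced by one record per
    qualifying target protein (scores copied).  Records whose protein has no
    qualifying ortholog are dropped.  Many-to-one collisions are collapsed to
    the per-channel maximum.
    """
    if min_methods < 1:
        raise ValidationError("min_methods must be >= 1")
    mapping: dict[str, list[str]] = {}
    for o in orthologs:
        if o.n_methods >= min_methods:
            mapping.setdefault(o.source_protein, []).append(o.target_protein)

    out: list[InteractionRecord] = []
    for rec in records:
        for target in mapping.get(rec.protein_id, ()):
            out.append(replace(rec, protein_id=target))
    return _collapse_duplicates(out)


# ---------------------------------------------------------------------------
# assembly


def build_network(
    records: Sequence[InteractionRecord],
    drug_whitelist: set[str] | None = None,
    protein_whitelist: set[str] | None = None,
    weight_channel: str = "combined",
) -> BipartiteNetwork:
    """Assemble the bipartite affinity matrix from interaction records.

    A record is included when no whitelist is given, or when its drug OR its
    protein appears in the respective whitelist.  Edge weight is the selected
    evidence channel; zero-weight records contribute no edge.  Node order is
    first-appearance order, drugs before proteins.
    """
    if weight_channel not in CHANNELS:
        raise ValidationError(f"unknown weight channel {weight_channel!r}")

    if drug_whitelist is None and protein_whitelist is None:
        selected = list(records)
    else:
        dw = drug_whitelist or set()
        pw = protein_whitelist or set()
        selected = [r for r in records if r.drug_id in dw or r.protein_id in pw]

    selected = [r for r in selected if getattr(r, weight_channel) > 0.0]
    if not selected:
        raise ConstructionError("no interaction records survive selection")

    drug_index: dict[str, int] = {}
    protein_index: dict[str, int] = {}
    for r in selected:
        drug_index.setdefault(r.drug_id, len(drug_index))
        protein_index.setdefault(r.protein_id, len(protein_index))
    m = len(drug_index)

    rows, cols, vals = [], [], []
    for r in selected:
        i = drug_index[r.drug_id]
        j = m + protein_index[r.protein_id]
        w = getattr(r, weight_channel)
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    size = m + len(protein_index)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()
    net = BipartiteNetwork(list(drug_index), list(protein_index), A)
    net.validate()
    return net


def prune_components(net: BipartiteNetwork) -> BipartiteNetwork:
    """Keep only the largest connected component.

    Ties are broken toward the component containing the smallest node index.
    Afterwards every node has degree > 0.
    """
    n_comp, labels = connected_components(net.A, directed=False)
    if n_comp <= 1:
        return net
    sizes = np.bincount(labels, minlength=n_comp)
    # ties: earliest-indexed node wins; labels are assigned in index order, so
    # the smallest label among the max-size components is the tie-break winner
    best = int(np.flatnonzero(sizes == sizes.max())[0])
    keep = np.flatnonzero(labels == best)
    m = net.n_drugs
    drug_keep = keep[keep < m]
    prot_keep = keep[keep >= m]
    sub = BipartiteNetwork(
        [net.drug_ids[i] for i in drug_keep],
        [net.protein_ids[i - m] for i in prot_keep],
        net.A[np.ix_(keep, keep)].tocsr(),
    )
    sub.validate()
    return sub


def transition_matrix(net: BipartiteNetwork) -> TransitionMatrix:
    """Row-normalize the affinity matrix: ``T = D^-1 A``.

    Invariant to uniform rescaling of the edge weights.
    """
    deg = net.degrees()
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        raise ValidationError(
            f"zero-degree node(s): {[net.node_ids[i] for i in zero[:5]]}"
        )
    T = sp.diags(1.0 / deg) @ net.A
    return TransitionMatrix(T.tocsr())


# ---------------------------------------------------------------------------
# serialization


def save_network(net: BipartiteNetwork, path: str | Path) -> None:
    """Write an edge-list TSV plus a JSON sidecar carrying the node order.

    The sidecar lives at ``<path>.json``; loading round-trips exactly.
    """
    path = Path(path)
    m = net.n_drugs
    coo = sp.triu(net.A).tocoo()
    lines = ["drug\tprotein\tweight"]
    order = np.lexsort((coo.col, coo.row))
    for i, j, w in zip(coo.row[order], coo.col[order], coo.data[order]):
        # triu of a bipartite drug-first matrix always has drug row, protein col
        lines.append(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{float(w)!r}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"drug_ids": net.drug_ids, "protein_ids": net.protein_ids}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def load_network(path: str | Path) -> BipartiteNetwork:
    """Load a network written by :func:`save_network`."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing node-order sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    drug_ids = list(sidecar["drug_ids"])
    protein_ids = list(sidecar["protein_ids"])
    idx = {nid: i for i, nid in enumerate(drug_ids + protein_ids)}

    # weights parsed by Python's float for exact repr round-tripping
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("drug", "protein", "weight") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    rows, cols, vals = [], [], []
    for r in df.itertuples(index=False):
        try:
            i, j = idx[r.drug], idx[r.protein]
        except KeyError as exc:
            raise FormatError(f"{path}: node {exc} absent from sidecar") from None
        w = float(r.weight)
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    size = len(idx)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()
    net = BipartiteNetwork(drug_ids, protein_ids, A)
    net.validate()
    return net
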