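"""Synthetic bipartite networks, labels and attribute matrices.

Planted-partition design: proteins are divided into modules, each module is
assigned to the effective or ineffective side, and drugs of a class attach to
their side's modules with probability ``p_within`` and elsewhere with
``p_between``.  Chemical attributes follow a class-dependent location model
so that the separability seen by similarity-based baselines is tunable.
All randomness flows through one generator seeded from the spec.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ConstructionError, ValidationError
from .network import BipartiteNetwork, prune_components
from .propagation import LabelSet
from .similarity import ChemicalProfile, TargetProfile, target_profiles_from_network

__all__ = ["SyntheticSpec", "generate_network", "generate_profiles"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module generator."""

    n_effective_drugs: int = 20
    n_ineffective_drugs: int = 200
    n_candidate_drugs: int = 100  # split evenly into effective/ineffective truth
    n_proteins: int = 500
    n_modules: int = 2
    p_within: float = 0.1
    p_between: float = 0.01
    weight_range: tuple[float, float] = (0.4, 1.0)
    attr_dim: int = 32
    class_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("weight_range must satisfy 0 < lo <= hi <= 1")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValidationError("need 0 <= p_between <= p_within <= 1")
        if self.n_modules < 2 or self.n_modules % 2:
            raise ValidationError("n_modules must be an even integer >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.class_shift < 0:
            raise ValidationError("class_shift must be >= 0")
        if min(self.n_effective_drugs, self.n_ineffective_drugs, self.n_proteins) < 1:
            raise ValidationError("need at least one drug per class and one protein")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(path).read_text())
        if "weight_range" in raw:
            raw["weight_range"] = tuple(raw["weight_range"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


def _drug_roster(spec: SyntheticSpec) -> tuple[list[str], dict[str, bool]]:
    """Drug ids in generation order plus the effective-class map.

    Seeds are named E####/N####, candidates C####; the first half of the
    candidates is planted effective-like.
    """
    eff = [f"E{i:04d}" for i in range(spec.n_effective_drugs)]
    ine = [f"N{i:04d}" for i in range(spec.n_ineffective_drugs)]
    cand = [f"C{i:04d}" for i in range(spec.n_candidate_drugs)]
    half = spec.n_candidate_drugs // 2
    is_effective = {d: True for d in eff}
    is_effective.update({d: False for d in ine})
    is_effective.update({d: i < half for i, d in enumerate(cand)})
    return eff + ine + cand, is_effective


def generate_network(
    spec: SyntheticSpec,
) -> tuple[BipartiteNetwork, LabelSet, dict[str, bool]]:
    """Generate a planted-module bipartite network with seed labels.

    Returns the pruned network (largest component), a :class:`LabelSet` of
    the surviving seed drugs, and the ground-truth effective-class map of
    the surviving candidate drugs.
    """
    rng = np.random.default_rng(spec.seed)
    drug_ids, is_effective = _drug_roster(spec)
    protein_ids = [f"P{i:04d}" for i in range(spec.n_proteins)]

    # contiguous protein modules, alternating side: even modules effective
    module_of = np.minimum(
        np.arange(spec.n_proteins) * spec.n_modules // spec.n_proteins,
        spec.n_modules - 1,
    )
    protein_is_effective = module_of % 2 == 0

    n_d, n_p = len(drug_ids), spec.n_proteins
    drug_side = np.array([is_effective[d] for d in drug_ids])
    match = drug_side[:, None] == protein_is_effective[None, :]
    prob = np.where(match, spec.p_within, spec.p_between)
    edges = rng.random((n_d, n_p)) < prob
    lo, hi = spec.weight_range
    weights = rng.uniform(lo, hi, size=(n_d, n_p)) * edges

    if not edges.any():
        raise ConstructionError("no edges generated; increase p_within")

    B = sp.csr_matrix(weights)
    size = n_d + n_p
    A = sp.bmat(
        [[sp.csr_matrix((n_d, n_d)), B], [B.T, sp.csr_matrix((n_p, n_p))]]
    ).tocsr()
    net = BipartiteNetwork(list(drug_ids), list(protein_ids), A)
    net = prune_components(net)
    net.validate()

    survivors = set(net.drug_ids)
    eff_seeds = frozenset(d for d in survivors if d.startswith("E"))
    ine_seeds = frozenset(d for d in survivors if d.startswith("N"))
    truth = {d: is_effective[d] for d in net.drug_ids if d.startswith("C")}
    if not eff_seeds or not ine_seeds:
        raise ConstructionError(
            "a seed class vanished after pruning; increase p_within"
        )
    labels = LabelSet(effective_drugs=eff_seeds, ineffective_drugs=ine_seeds)
    return net, labels, truth


def generate_profiles(
    class_of: dict[str, bool],
    spec: SyntheticSpec,
    net: BipartiteNetwork | None = None,
) -> tuple[list[ChemicalProfile], list[TargetProfile]]:
    """Generate attribute vectors whose class separation tracks ``class_shift``.

    Continuous descriptors are Normal(1, noise_sd) everywhere except that the
    effective class is shifted by ``class_shift`` on the second half of the
    dimensions and the ineffective class on the first half, so the two class
    directions diverge (a uniform shift would be nearly invisible to cosine
    similarity).  Fingerprint bits are Bernoulli with class-shifted rates.
    At ``class_shift == 0`` the two classes are identically distributed.
    Target profiles are read off ``net`` when given (restricted to drugs in
    ``class_of``).
    """
    rng = np.random.default_rng(spec.seed + 1)  # decouple from network draws
    ids = list(class_of)
    n = len(ids)
    side = np.array([class_of[d] for d in ids])

    half = spec.attr_dim // 2
    mean = np.ones((n, spec.attr_dim))
    mean[side, half:] += spec.class_shift
    mean[~side, :half] += spec.class_shift
    cont = rng.normal(mean, spec.noise_sd)
    rate = np.where(
        side,
        np.clip(0.5 + 0.04 * spec.class_shift, 0.05, 0.95),
        np.clip(0.5 - 0.04 * spec.class_shift, 0.05, 0.95),
    )
    bits = (rng.random((n, spec.attr_dim)) < rate[:, None]).astype(float)
    X = np.hstack([cont, bits])
    chemical = [ChemicalProfile(d, X[i]) for i, d in enumerate(ids)]

    targets: list[TargetProfile] = []
    if net is not None:
        by_id = {p.drug_id: p for p in target_profiles_from_network(net)}
        targets = [by_id[d] for d in ids if d in by_id]
    return chemical, targets
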