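"""Shared fixtures: hand-built records, networks, and the mirrored fixture."""

import numpy as np
import pytest
import scipy.sparse as sp

from rwrscreen.network import BipartiteNetwork, InteractionRecord
from rwrscreen.propagation import LabelSet


def make_network(edges, drug_ids=None, protein_ids=None):
    """Build a BipartiteNetwork from (drug, protein, weight) triples."""
    if drug_ids is None:
        drug_ids = list(dict.fromkeys(d for d, _, _ in edges))
    if protein_ids is None:
        protein_ids = list(dict.fromkeys(p for _, p, _ in edges))
    idx = {n: i for i, n in enumerate(list(drug_ids) + list(protein_ids))}
    size = len(idx)
    A = np.zeros((size, size))
    for d, p, w in edges:
        A[idx[d], idx[p]] = A[idx[p], idx[d]] = w
    return BipartiteNetwork(list(drug_ids), list(protein_ids), sp.csr_matrix(A))


@pytest.fixture
def star_network():
    """One drug tied to two proteins with weights 1 and 3."""
    return make_network([("d1", "p1", 1.0), ("d1", "p2", 3.0)])


@pytest.fixture
def two_node_network():
    """Single drug-protein edge; the analytic 2x2 fixture."""
    return make_network([("d1", "p1", 1.0)])


@pytest.fixture
def mirrored_network():
    """Network with an automorphism swapping the effective/ineffective halves.

    dE-pE and dI-pI mirror each other; bridge drug dB touches both proteins.
    """
    net = make_network(
        [
            ("dE", "pE", 1.0),
            ("dI", "pI", 1.0),
            ("dB", "pE", 1.0),
            ("dB", "pI", 1.0),
        ]
    )
    labels = LabelSet(effective_drugs={"dE"}, ineffective_drugs={"dI"})
    sigma = {"dE": "dI", "dI": "dE", "pE": "pI", "pI": "pE", "dB": "dB"}
    return net, labels, sigma


@pytest.fixture
def ten_record_fixture():
    """Hand-built 10-record ingestion fixture for the composed pipeline test.

    After evidence filtering (experimental or database > 0), ortholog mapping
    (>= 2 methods) and network assembly, the surviving subgraph has one
    component {d1, d2, W1, W2} plus a smaller component {d4, W4} that the
    pruning step must drop.
    """
    records = [
        InteractionRecord("d1", "H1", experimental=0.8, combined=0.9),
        InteractionRecord("d1", "H2", database=0.7, combined=0.7),
        InteractionRecord("d2", "H1", experimental=0.5, combined=0.6),
        InteractionRecord("d2", "H3", textmining=0.9, combined=0.9),  # filtered out
        InteractionRecord("d3", "H5", experimental=0.4, combined=0.4),  # H5 unmapped
        InteractionRecord("d4", "H4", database=0.3, combined=0.5),
        InteractionRecord("d5", "H1", predicted=0.9, combined=0.9),  # filtered out
        InteractionRecord("d1", "H1", experimental=0.6, combined=0.4),  # dup, collapsed
        InteractionRecord("d2", "H2", database=0.2, combined=0.3),
        InteractionRecord("d6", "H6", combined=0.8),  # no evidence, filtered out
    ]
    orthologs = [
        ("H1", "W1", 3),
        ("H2", "W2", 2),
        ("H3", "W3", 4),
        ("H4", "W4", 2),
        ("H5", "W5", 1),  # below the 2-method cut
    ]
    return records, orthologs
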