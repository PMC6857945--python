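"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mdbirw.data import AssociationNetwork, DiseaseDAG, NodeRegistry
from mdbirw.fixtures import FixtureSpec, make_association_matrix, make_dag_forest


def straightline_birw(MS, DS, A, alpha, l, r, strict=False):
    """Independent straight-line transcription of the bi-random-walks algorithm.

    Deliberately non-modular: Laplacian normalization and the iteration are
    written inline with explicit loops over iterations, mirroring the
    pseudocode line by line (with per-iteration flag gating unless ``strict``).
    """
    MS = np.asarray(MS, float)
    DS = np.asarray(DS, float)
    A = np.asarray(A, float)

    def lap(S):
        out = S.astype(float).copy()
        deg = S.sum(axis=1)
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                if deg[i] > 0 and deg[j] > 0:
                    out[i, j] = S[i, j] / np.sqrt(deg[i] * deg[j])
                else:
                    out[i, j] = 0.0
        return out

    MSn = lap(MS)
    DSn = lap(DS)
    A0 = A / A.sum()
    RM = A0.copy()
    RD = A0.copy()
    R = A0.copy()
    for t in range(1, max(l, r) + 1):
        flagm = flagd = 1 if strict else 0
        if t <= l:
            RM = alpha * MSn.dot(RM) + (1 - alpha) * A0
            flagm = 1
        if t <= r:
            RD = alpha * RD.dot(DSn) + (1 - alpha) * A0
            flagd = 1
        R = (flagm * RM + flagd * RD) / (flagm + flagd)
    return R


def pairwise_auc(labels, scores):
    """Brute-force Mann–Whitney AUC: P(pos > neg) + 0.5·P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_similarity(rng, n):
    """Random symmetric [0,1] similarity matrix with unit diagonal."""
    X = rng.random((n, n))
    S = (X + X.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def chain_dag(disease="d", ancestors=("p", "g")):
    """Ancestor chain g -> p -> d (deepest ancestor listed last)."""
    nodes = {disease, *ancestors}
    edges = {}
    chain = list(ancestors[::-1]) + [disease]  # root ... -> disease
    for parent, child in zip(chain, chain[1:]):
        edges[parent] = frozenset({child})
    return DiseaseDAG(disease, frozenset(nodes), edges)


@pytest.fixture
def small_spec():
    return FixtureSpec(n_metabolites=12, n_diseases=8, n_blocks=2, seed=7)


@pytest.fixture
def small_network(small_spec):
    return make_association_matrix(small_spec)


@pytest.fixture
def small_forest(small_spec):
    return make_dag_forest(small_spec)


@pytest.fixture
def tiny_network():
    """Hand-built 3-metabolite x 2-disease network."""
    mets = NodeRegistry("metabolite", ("ma", "mb", "mc"))
    dis = NodeRegistry("disease", ("da", "db"))
    A = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return AssociationNetwork(mets, dis, A)
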