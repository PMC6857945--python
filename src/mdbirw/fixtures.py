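"""Synthetic fixture generators: DAG forests, planted-block association matrices,
and the four-node worked example of the heterogeneous network.

The generators emulate the statistical premise behind guilt-by-association
link prediction — metabolites with similar functions tend to associate with
the same or semantically similar diseases — as a planted block model: the
metabolite and disease registries are split into aligned blocks, association
density is high inside a block and low outside, and diseases of one block
share a deep ancestor chain in the DAG forest so their semantic similarity is
high while cross-block similarity is zero. The planted structure gives a
known recoverable signal for cross-validation checks.

All generators are seed-deterministic and emit the same file formats the
data module reads, so fixtures double as I/O round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AssociationNetwork, DiseaseDAG, NodeRegistry
from .similarity import SimilarityMatrix

__all__ = [
    "FixtureSpec",
    "make_dag_forest",
    "make_association_matrix",
    "make_fig_example",
    "write_fixture_files",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-block fixture.

    Defaults give the 40-metabolite × 20-disease, four-block instance used by
    the recovery checks: within-block association density 0.8 against a 0.02
    background, and disease DAG chains of depth 3 per block.
    """

    n_metabolites: int = 40
    n_diseases: int = 20
    n_blocks: int = 4
    within_block_density: float = 0.8
    background_density: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_block_density", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_block_density <= self.background_density:
            raise ValueError("within_block_density must exceed background_density")
        if self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("dag_depth and dag_branching must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


def _disease_ids(spec: FixtureSpec) -> list[str]:
    return [f"D{j:03d}" for j in range(spec.n_diseases)]


def _metabolite_ids(spec: FixtureSpec) -> list[str]:
    return [f"M{i:04d}" for i in range(spec.n_metabolites)]


def _blocks(n: int, n_blocks: int) -> list[np.ndarray]:
    return list(np.array_split(np.arange(n), n_blocks))


def make_dag_forest(spec: FixtureSpec) -> dict[str, DiseaseDAG]:
    """Build a deterministic DAG forest with block-shared ancestor trees.

    All diseases share a single global root; each block adds a balanced
    ancestor tree beneath it (the block root at level 1, each deeper level
    multiplying the node count by the branching factor, depth − 2 block
    levels in total). Diseases attach round-robin to the deepest block level,
    so same-block diseases share long ancestor chains (high semantic
    similarity) while diseases of different blocks share only the global root
    (low but nonzero similarity). With depth 1 every disease is an isolated
    root and the semantic similarity matrix is the identity; with depth 2
    diseases hang directly off the shared root.
    """
    ids = _disease_ids(spec)
    forest: dict[str, DiseaseDAG] = {}
    root = "ROOT"
    for b, block in enumerate(_blocks(spec.n_diseases, spec.n_blocks)):
        if spec.dag_depth == 1:
            for j in block:
                d = ids[j]
                forest[d] = DiseaseDAG(d, frozenset({d}), {})
            continue
        # block-internal levels 1..depth-2 under the root; level k has
        # branching**(k-1) terms
        levels: list[list[str]] = [[root]]
        for k in range(1, spec.dag_depth - 1):
            levels.append([f"B{b}L{k}N{i}" for i in range(spec.dag_branching ** (k - 1))])
        deepest = levels[-1]
        for pos, j in enumerate(block):
            d = ids[j]
            idx = pos % len(deepest)
            # ancestor chain from the anchor up to the global root
            chain = []
            for k in range(len(levels) - 1, -1, -1):
                chain.append(levels[k][idx])
                idx //= spec.dag_branching
            terms = frozenset(chain) | {d}
            path = chain[::-1] + [d]  # root ... anchor, disease
            d_edges = {p: frozenset({c}) for p, c in zip(path, path[1:])}
            forest[d] = DiseaseDAG(d, terms, d_edges)
    return forest


def make_association_matrix(spec: FixtureSpec) -> AssociationNetwork:
    """Sample a planted-block binary association matrix.

    Block-aligned cells are Bernoulli(within_block_density), all others
    Bernoulli(background_density). Every metabolite is guaranteed at least
    one association: an all-zero row gets a single random within-block entry.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_metabolites, spec.n_diseases
    met_blocks = _blocks(m, spec.n_blocks)
    dis_blocks = _blocks(n, spec.n_blocks)
    P = np.full((m, n), spec.background_density)
    for mb, db in zip(met_blocks, dis_blocks):
        P[np.ix_(mb, db)] = spec.within_block_density
    A = (rng.random((m, n)) < P).astype(float)
    block_of = np.concatenate([np.full(len(mb), b) for b, mb in enumerate(met_blocks)])
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        db = dis_blocks[int(block_of[i])]
        A[i, rng.choice(db)] = 1.0
    return AssociationNetwork(
        NodeRegistry("metabolite", tuple(_metabolite_ids(spec))),
        NodeRegistry("disease", tuple(_disease_ids(spec))),
        A,
    )


def make_fig_example() -> tuple[AssociationNetwork, SimilarityMatrix, SimilarityMatrix]:
    """Fixed 4-metabolite × 4-disease heterogeneous-network example.

    Encodes the canonical two-path prediction story: metabolites m1 and m4
    are highly similar (MS = 0.9) and m1 has a known association with d2;
    diseases d2 and d4 are highly similar and m4 is known to associate with
    d4. Both walk directions therefore accumulate probability on the unknown
    (m4, d2) cell, while (m3, d3) — whose endpoints have no similar connected
    neighbours — stays low. Returns (network, DS, MS).
    """
    mets = NodeRegistry("metabolite", ("m1", "m2", "m3", "m4"))
    dis = NodeRegistry("disease", ("d1", "d2", "d3", "d4"))
    A = np.zeros((4, 4))
    A[0, 1] = 1.0  # m1 - d2
    A[3, 3] = 1.0  # m4 - d4
    A[1, 0] = 1.0  # m2 - d1
    network = AssociationNetwork(mets, dis, A)
    MS = np.full((4, 4), 0.1)
    np.fill_diagonal(MS, 1.0)
    MS[0, 3] = MS[3, 0] = 0.9
    DS = np.full((4, 4), 0.1)
    np.fill_diagonal(DS, 1.0)
    DS[1, 3] = DS[3, 1] = 0.9
    return (
        network,
        SimilarityMatrix("disease", "integrated", DS),
        SimilarityMatrix("metabolite", "integrated", MS),
    )


def write_fixture_files(spec: FixtureSpec, out_dir) -> tuple[Path, Path]:
    """Write associations.tsv and dag_edges.tsv in the data module's formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network = make_association_matrix(spec)
    rows, cols = np.nonzero(network.A)
    pd.DataFrame(
        {
            "metabolite_id": [network.metabolites.ids[i] for i in rows],
            "disease_id": [network.diseases.ids[j] for j in cols],
        }
    ).to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    forest = make_dag_forest(spec)
    edges = []
    for dag in forest.values():
        for parent, children in dag.child_edges.items():
            for child in sorted(children):
                edges.append((parent, child))
    pd.DataFrame(sorted(set(edges)), columns=["parent", "child"]).to_csv(
        out_dir / "dag_edges.tsv", sep="\t", index=False
    )
    return out_dir / "associations.tsv", out_dir / "dag_edges.tsv"
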