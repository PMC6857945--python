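"""Registries, matrices and readers/writers for associations, disease DAGs and scores.

The central in-memory objects are:

* :class:`NodeRegistry` — an ordered, de-duplicated list of node identifiers
  (metabolites or diseases) with an id → row/column index map.
* :class:`AssociationNetwork` — the bipartite binary association matrix ``A``
  with rows indexed by metabolites and columns by diseases.
* :class:`DiseaseDAG` — one disease's ancestor graph ``(d, T(d), E(d))``,
  with edges oriented parent → child, used by the semantic similarity engine.

Matrix orientation is rows = metabolites, columns = diseases throughout the
package: the left (metabolite-side) walk multiplies the metabolite similarity
matrix (m×m) into ``A`` from the left, the right (disease-side) walk
multiplies the disease similarity matrix (n×n) from the right, and both only
conform under this orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRegistry",
    "AssociationNetwork",
    "DiseaseDAG",
    "load_associations",
    "load_disease_dags",
    "expand_tree_numbers",
    "write_scores",
    "read_scores",
    "write_similarity",
    "read_similarity",
]


class FormatError(ValueError):
    """Raised when an input file does not have the expected structure."""


@dataclass(frozen=True)
class NodeRegistry:
    """Ordered registry of unique node identifiers of one kind."""

    kind: str  # "metabolite" or "disease"
    ids: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate ids in {self.kind} registry")
        object.__setattr__(self, "index", {i: k for k, i in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.index


@dataclass
class AssociationNetwork:
    """Bipartite metabolite–disease association network.

    ``A`` is an (m, n) array with ``A[i, j] = 1`` iff metabolite ``i`` has a
    recorded association with disease ``j``.
    """

    metabolites: NodeRegistry
    diseases: NodeRegistry
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        m, n = len(self.metabolites), len(self.diseases)
        if self.A.shape != (m, n):
            raise ValueError(f"A has shape {self.A.shape}, expected {(m, n)}")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (metabolite row, disease column) of known associations."""
        rows, cols = np.nonzero(self.A)
        return list(zip(rows.tolist(), cols.tolist()))

    def copy(self) -> "AssociationNetwork":
        return AssociationNetwork(self.metabolites, self.diseases, self.A.copy())


@dataclass
class DiseaseDAG:
    """Ancestor DAG of one disease: the term set T(d) and parent→child edges E(d).

    ``nodes`` always contains the disease itself; ``child_edges[t]`` is the set
    of children of ``t`` restricted to this DAG.
    """

    disease: str
    nodes: frozenset[str]
    child_edges: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.disease not in self.nodes:
            raise ValueError(f"disease {self.disease!r} missing from its own DAG")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for parent, children in self.child_edges.items():
            for child in children:
                if parent not in self.nodes or child not in self.nodes:
                    raise ValueError("DAG edge endpoint outside the term set")
                g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError(f"cycle in DAG of disease {self.disease!r}")

    def children(self, term: str) -> frozenset[str]:
        return self.child_edges.get(term, frozenset())


def load_associations(
    path,
    metabolite_col: str = "metabolite_id",
    disease_col: str = "disease_id",
    sep: str | None = None,
) -> AssociationNetwork:
    """Load a metabolite–disease association table into a binary network.

    Accepts TSV/CSV (delimiter sniffed unless ``sep`` is given) and, when
    openpyxl is installed, ``.xls``/``.xlsx`` tables. Identifiers are matched
    exactly after whitespace trimming; duplicate pairs are dropped with a
    logged count; registries are built in first-appearance order.
    """
    path = str(path)
    if path.endswith((".xls", ".xlsx")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in (metabolite_col, disease_col) if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing}; found {list(df.columns)}")
    df = df[[metabolite_col, disease_col]].dropna()
    if df.empty:
        raise FormatError(f"no associations found in {path}")
    pairs = list(
        zip(df[metabolite_col].astype(str).str.strip(), df[disease_col].astype(str).str.strip())
    )
    unique_pairs = list(dict.fromkeys(pairs))
    n_dup = len(pairs) - len(unique_pairs)
    if n_dup:
        logger.info("dropped %d duplicate association(s) from %s", n_dup, path)
    metabolites = NodeRegistry("metabolite", tuple(dict.fromkeys(p[0] for p in unique_pairs)))
    diseases = NodeRegistry("disease", tuple(dict.fromkeys(p[1] for p in unique_pairs)))
    A = np.zeros((len(metabolites), len(diseases)))
    for met, dis in unique_pairs:
        A[metabolites.index[met], diseases.index[dis]] = 1.0
    return AssociationNetwork(metabolites, diseases, A)


def expand_tree_numbers(disease: str, tree_numbers: list[str]) -> DiseaseDAG:
    """Build a disease DAG from MeSH-style dotted tree numbers.

    Every dot-separated prefix of every tree number becomes an ancestor term;
    the union over all tree positions forms T(d), and each full tree number is
    connected to the disease itself. Example: tree numbers ``C10.228`` and
    ``C14.907`` yield ancestors {C10, C10.228, C14, C14.907} plus the disease.
    """
    nodes: set[str] = {disease}
    edges: dict[str, set[str]] = {}
    for tn in tree_numbers:
        tn = tn.strip()
        if not tn:
            continue
        parts = tn.split(".")
        chain = [".".join(parts[: k + 1]) for k in range(len(parts))]
        nodes.update(chain)
        for parent, child in zip(chain, chain[1:]):
            edges.setdefault(parent, set()).add(child)
        edges.setdefault(chain[-1], set()).add(disease)
    return DiseaseDAG(disease, frozenset(nodes), {p: frozenset(c) for p, c in edges.items()})


def load_disease_dags(path, tree_numbers: bool | None = None) -> dict[str, DiseaseDAG]:
    """Load disease DAGs from a two-column TSV.

    Two layouts are accepted:

    * edge list with columns ``parent``, ``child`` — a single global hierarchy
      from which each disease's ancestor closure is extracted (every node that
      appears as a child of something, or at all, gets a DAG);
    * tree-number table with columns ``disease``, ``tree_number`` — each row
      assigns a MeSH-style dotted position to a disease, expanded with
      :func:`expand_tree_numbers` and unioned per disease.

    Layout is chosen from the header unless ``tree_numbers`` is forced.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).dropna()
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if tree_numbers is None:
        tree_numbers = "tree_number" in cols
    if tree_numbers:
        if not {"disease", "tree_number"} <= set(cols):
            raise FormatError(f"expected columns disease/tree_number, found {cols}")
        out: dict[str, DiseaseDAG] = {}
        for disease, grp in df.groupby("disease", sort=False):
            out[disease.strip()] = expand_tree_numbers(
                disease.strip(), grp["tree_number"].tolist()
            )
        return out
    if not {"parent", "child"} <= set(cols):
        raise FormatError(f"expected columns parent/child, found {cols}")
    g = nx.DiGraph()
    for parent, child in zip(df["parent"].str.strip(), df["child"].str.strip()):
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise FormatError(f"hierarchy in {path} contains a cycle")
    dags: dict[str, DiseaseDAG] = {}
    for node in g.nodes:
        terms = nx.ancestors(g, node) | {node}
        sub = g.subgraph(terms)
        child_edges: dict[str, set[str]] = {}
        for parent, child in sub.edges:
            child_edges.setdefault(parent, set()).add(child)
        dags[node] = DiseaseDAG(
            node, frozenset(terms), {p: frozenset(c) for p, c in child_edges.items()}
        )
    return dags


def write_scores(
    R: np.ndarray,
    network: AssociationNetwork,
    path,
    sort_per_disease: bool = False,
) -> None:
    """Write a score matrix as TSV ``metabolite_id  disease_id  score``.

    With ``sort_per_disease`` the rows are grouped by disease and sorted by
    descending score (ties broken by registry order), matching the ranking
    operation's output order.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != network.A.shape:
        raise ValueError(f"score matrix shape {R.shape} != {network.A.shape}")
    mets = np.array(network.metabolites.ids)
    rows = []
    if sort_per_disease:
        for j, dis in enumerate(network.diseases.ids):
            order = np.argsort(-R[:, j], kind="stable")
            rows.append(
                pd.DataFrame(
                    {"metabolite_id": mets[order], "disease_id": dis, "score": R[order, j]}
                )
            )
    else:
        for j, dis in enumerate(network.diseases.ids):
            rows.append(
                pd.DataFrame({"metabolite_id": mets, "disease_id": dis, "score": R[:, j]})
            )
    pd.concat(rows, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_scores(path, network: AssociationNetwork) -> np.ndarray:
    """Read a score TSV back into an (m, n) matrix aligned to the registries."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    R = np.zeros(network.A.shape)
    mi = network.metabolites.index
    di = network.diseases.index
    for met, dis, score in zip(df["metabolite_id"], df["disease_id"], df["score"]):
        R[mi[str(met)], di[str(dis)]] = score
    return R


def write_similarity(values: np.ndarray, ids, path) -> None:
    """Write a square similarity matrix as TSV with id header row and column."""
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_similarity(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)
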