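"""Similarity engines: disease semantic, metabolite functional, GIP kernel, integration.

Four similarity constructions feed the bi-random walks:

* **Disease semantic similarity** ``S^d`` from per-disease ancestor DAGs.
  Each term t in T(d) receives a contribution ``D_d(t)``: 1 at the disease
  itself, otherwise the maximum over its children of the decay factor Δ times
  the child's contribution. The semantic value DV(d) sums the contributions,
  and the similarity of two diseases is the sum of both contributions over the
  shared terms divided by DV(d_i) + DV(d_j).
* **Metabolite functional similarity** ``S^m`` (MISIM-style): two metabolites
  are similar to the extent that each disease associated with one has a highly
  semantically similar disease associated with the other (group-max averaging).
* **GIP kernel similarity**: a Gaussian kernel over binary interaction
  profiles (rows/columns of the association matrix) whose bandwidth is the
  base bandwidth divided by the mean squared profile norm.
* **Integration**: where the semantic/functional value is zero the GIP value
  substitutes; elsewhere the two are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import AssociationNetwork, DiseaseDAG

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticParams",
    "GipParams",
    "SimilarityMatrix",
    "semantic_contribution",
    "semantic_value",
    "disease_semantic_similarity",
    "disease_to_group_similarity",
    "metabolite_functional_similarity",
    "gip_kernel",
    "integrate_similarity",
    "build_similarity_networks",
]


@dataclass(frozen=True)
class SemanticParams:
    """Semantic-contribution decay factor Δ (default 0.5)."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")


@dataclass(frozen=True)
class GipParams:
    """Base GIP bandwidth λ' (dimensionless, default 1)."""

    bandwidth_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth_prime <= 0:
            raise ValueError(f"bandwidth_prime must be > 0, got {self.bandwidth_prime}")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one node registry.

    ``source`` records the provenance: semantic, functional, gip, integrated
    or normalized. Entries lie in [0, 1] for all sources except normalized
    (where row scaling can shrink values but never makes them negative).
    """

    kind: str  # node type: "metabolite" or "disease"
    source: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {v.shape}")
        if self.source != "normalized":
            if not np.allclose(v, v.T, atol=1e-12):
                raise ValueError("similarity matrix must be symmetric")
            if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
                raise ValueError(f"{self.source} similarity entries outside [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def semantic_contribution(
    dag: DiseaseDAG, term: str, params: SemanticParams = SemanticParams()
) -> float:
    """Contribution ``D_d(term)`` of one ancestor term within a disease's DAG.

    The disease itself contributes 1; any other term contributes Δ times the
    best contribution among its children in the DAG. Evaluated by memoized
    depth-first recursion with a cycle guard.
    """
    if term not in dag.nodes:
        raise ValueError(f"term {term!r} not in DAG of {dag.disease!r}")
    return _contributions(dag, params.delta)[term]


def _contributions(dag: DiseaseDAG, delta: float) -> dict[str, float]:
    memo: dict[str, float] = {}
    in_progress: set[str] = set()

    def visit(t: str) -> float:
        if t in memo:
            return memo[t]
        if t in in_progress:
            raise ValueError(f"cycle through {t!r} in DAG of {dag.disease!r}")
        in_progress.add(t)
        if t == dag.disease:
            val = 1.0
        else:
            children = dag.children(t)
            if not children:
                # term not on any path to the disease: contributes nothing
                val = 0.0
            else:
                val = delta * max(visit(c) for c in children)
        in_progress.discard(t)
        memo[t] = val
        return val

    for t in dag.nodes:
        visit(t)
    return memo


def semantic_value(dag: DiseaseDAG, params: SemanticParams = SemanticParams()) -> float:
    """Semantic value DV(d): the sum of contributions over all terms in T(d)."""
    return float(sum(_contributions(dag, params.delta).values()))


def disease_semantic_similarity(
    dags: dict[str, DiseaseDAG],
    disease_ids,
    params: SemanticParams = SemanticParams(),
) -> SimilarityMatrix:
    """Pairwise semantic similarity matrix S^d over an ordered disease registry.

    Diseases absent from ``dags`` get a zero row/column except the unit
    diagonal, so that downstream integration falls back to the GIP kernel.
    """
    disease_ids = list(disease_ids)
    n = len(disease_ids)
    contrib = {}
    dv = {}
    for d in disease_ids:
        if d in dags:
            contrib[d] = _contributions(dags[d], params.delta)
            dv[d] = sum(contrib[d].values())
    missing = [d for d in disease_ids if d not in dags]
    if missing:
        logger.warning(
            "%d disease(s) without a DAG; their semantic rows are zero", len(missing)
        )
    S = np.zeros((n, n))
    for i, di in enumerate(disease_ids):
        if di not in contrib:
            continue
        ci = contrib[di]
        for j in range(i, n):
            dj = disease_ids[j]
            if dj not in contrib:
                continue
            cj = contrib[dj]
            shared = ci.keys() & cj.keys()
            if not shared:
                continue
            num = sum(ci[t] + cj[t] for t in shared)
            S[i, j] = S[j, i] = num / (dv[di] + dv[dj])
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix("disease", "semantic", S)


def disease_to_group_similarity(d: str, group, S: SimilarityMatrix, ids) -> float:
    """Max similarity between disease ``d`` and a non-empty disease group."""
    group = list(group)
    if not group:
        raise ValueError("disease group must be non-empty")
    index = {x: k for k, x in enumerate(ids)}
    return float(max(S.values[index[d], index[g]] for g in group))


def metabolite_functional_similarity(
    network: AssociationNetwork, S_d: SimilarityMatrix
) -> SimilarityMatrix:
    """MISIM-style metabolite functional similarity S^m from disease semantics.

    For metabolites i, j with disease sets D_i, D_j of sizes num_i, num_j:

        S^m(i,j) = [ Σ_{d∈D_i} max_{d'∈D_j} S(d,d') +
                     Σ_{d∈D_j} max_{d'∈D_i} S(d,d') ] / (num_i + num_j)

    A pair where both metabolites have empty disease sets is defined as 0
    (integration then substitutes the GIP value).
    """
    A = network.A
    S = S_d.values
    m = A.shape[0]
    num = A.sum(axis=1)  # diseases per metabolite
    # GM[d, j] = max over j's diseases of S(d, ·); zero when j has none
    GM = np.zeros((A.shape[1], m))
    for j in range(m):
        mask = A[j] > 0
        if mask.any():
            GM[:, j] = S[:, mask].max(axis=1)
    B = A @ GM  # B[i, j] = Σ_{d∈D_i} S(d, D_j)
    denom = num[:, None] + num[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        Sm = np.where(denom > 0, (B + B.T) / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(Sm, np.where(num > 0, 1.0, 0.0))
    Sm = np.clip((Sm + Sm.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix("metabolite", "functional", Sm)


def gip_kernel(
    profiles: np.ndarray, kind: str, params: GipParams = GipParams()
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    The bandwidth is λ = λ' / mean_i ‖IP_i‖², and the kernel value is
    exp(−λ‖IP_i − IP_j‖²). When every profile is all-zero the mean norm
    vanishes; the kernel is then returned as the identity with a warning so
    that downstream integration and normalization stay defined.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D array")
    mean_sq_norm = float((P**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        logger.warning("all interaction profiles are zero; GIP kernel set to identity")
        return SimilarityMatrix(kind, "gip", np.eye(P.shape[0]))
    lam = params.bandwidth_prime / mean_sq_norm
    sq_dists = squareform(pdist(P, metric="sqeuclidean"))
    K = np.exp(-lam * sq_dists)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(kind, "gip", K)


def integrate_similarity(base: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Merge a semantic/functional matrix with its GIP counterpart.

    Entry-wise: where the base value is zero the GIP value is used; elsewhere
    the two are averaged. The diagonal is forced to 1.
    """
    if base.values.shape != gip.values.shape:
        raise ValueError("similarity matrices must have matching shapes")
    if base.kind != gip.kind:
        raise ValueError("cannot integrate matrices over different node types")
    b, g = base.values, gip.values
    out = np.where(b == 0.0, g, (b + g) / 2.0)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(base.kind, "integrated", out)


def build_similarity_networks(
    network: AssociationNetwork,
    dags: dict[str, DiseaseDAG],
    semantic_params: SemanticParams = SemanticParams(),
    gip_params: GipParams = GipParams(),
    S_d: SimilarityMatrix | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build the integrated metabolite (MS) and disease (DS) similarity networks.

    Pass a precomputed ``S_d`` to skip the semantic step (it does not depend
    on the association matrix, so cross-validation reuses it across folds).
    Returns ``(MS, DS)``.
    """
    if S_d is None:
        S_d = disease_semantic_similarity(dags, network.diseases.ids, semantic_params)
    S_m = metabolite_functional_similarity(network, S_d)
    GS_m = gip_kernel(network.A, "metabolite", gip_params)
    GS_d = gip_kernel(network.A.T, "disease", gip_params)
    MS = integrate_similarity(S_m, GS_m)
    DS = integrate_similarity(S_d, GS_d)
    return MS, DS
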