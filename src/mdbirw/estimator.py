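"""Scikit-learn style estimator wrapping the full similarity + walk pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .birw import WalkParams, birw_predict
from .data import AssociationNetwork, DiseaseDAG
from .similarity import (
    GipParams,
    SemanticParams,
    SimilarityMatrix,
    build_similarity_networks,
)

__all__ = ["MDBIRW"]


class MDBIRW(BaseEstimator):
    """Bi-random-walks predictor of metabolite–disease association scores.

    The estimator takes a binary association matrix (rows = metabolites,
    columns = diseases) plus per-disease ancestor DAGs, builds the integrated
    metabolite and disease similarity networks (semantic / MISIM-style
    functional similarity merged with Gaussian interaction-profile kernels),
    and propagates the associations through both networks with independently
    bounded step counts.

    Parameters
    ----------
    alpha : float, default 0.3
        Walk decay factor: weight of the propagated term against the restart
        term (1 − alpha) · A at every step.
    l, r : int, default 3
        Maximum step counts of the metabolite-side and disease-side walks.
    delta : float, default 0.5
        Semantic contribution decay per ancestor level in the disease DAGs.
    bandwidth_prime : float, default 1.0
        Base GIP bandwidth, divided by the mean squared profile norm.
    normalization : {"laplacian", "row"}, default "laplacian"
        How the similarity networks are normalized before propagation.
    strict_pseudocode : bool, default False
        Average stale walk matrices once a step bound is exhausted instead of
        dropping them from the combination.

    Attributes
    ----------
    scores_ : ndarray of shape (m, n)
        Predicted association score matrix after :meth:`fit`.
    MS_, DS_ : SimilarityMatrix
        Integrated metabolite and disease similarity networks.
    network_ : AssociationNetwork or None
        The fitted network when registries were supplied.

    Examples
    --------
    >>> from mdbirw.fixtures import FixtureSpec, make_association_matrix, make_dag_forest
    >>> spec = FixtureSpec(n_metabolites=12, n_diseases=6, n_blocks=2, seed=0)
    >>> net = make_association_matrix(spec)
    >>> model = MDBIRW(alpha=0.3, l=3, r=3).fit(net.A, dags=make_dag_forest(spec),
    ...                                         disease_ids=net.diseases.ids)
    >>> model.scores_.shape
    (12, 6)
    """

    def __init__(
        self,
        alpha: float = 0.3,
        l: int = 3,
        r: int = 3,
        delta: float = 0.5,
        bandwidth_prime: float = 1.0,
        normalization: str = "laplacian",
        strict_pseudocode: bool = False,
    ):
        self.alpha = alpha
        self.l = l
        self.r = r
        self.delta = delta
        self.bandwidth_prime = bandwidth_prime
        self.normalization = normalization
        self.strict_pseudocode = strict_pseudocode

    def _walk_params(self) -> WalkParams:
        return WalkParams(
            alpha=self.alpha,
            l=self.l,
            r=self.r,
            normalization=self.normalization,
            strict_pseudocode=self.strict_pseudocode,
        )

    def fit(
        self,
        X,
        y=None,
        *,
        dags: dict[str, DiseaseDAG] | None = None,
        disease_ids=None,
        S_d: SimilarityMatrix | None = None,
    ):
        """Build similarity networks from X and run the bi-random walks.

        Parameters
        ----------
        X : AssociationNetwork or binary array of shape (m, n)
            Known associations; rows are metabolites, columns diseases.
        dags : mapping disease id -> DiseaseDAG, optional
            Ancestor DAGs for semantic similarity. Diseases without a DAG get
            zero semantic similarity and fall back to the GIP kernel.
        disease_ids : sequence of str, optional
            Column identifiers when X is a bare array; defaults to column
            indices as strings.
        S_d : SimilarityMatrix, optional
            Precomputed disease semantic similarity (it does not depend on X,
            so cross-validation can reuse it across folds).
        """
        self._walk_params()  # validate eagerly
        if isinstance(X, AssociationNetwork):
            network = X
            self.network_ = X
        else:
            A = np.asarray(X, dtype=float)
            if A.ndim != 2:
                raise ValueError(f"X must be 2-D, got shape {A.shape}")
            if not np.isin(A, (0.0, 1.0)).all():
                raise ValueError("X must be a binary association matrix")
            if disease_ids is None:
                disease_ids = tuple(str(j) for j in range(A.shape[1]))
            from .data import NodeRegistry

            network = AssociationNetwork(
                NodeRegistry("metabolite", tuple(f"m{i}" for i in range(A.shape[0]))),
                NodeRegistry("disease", tuple(disease_ids)),
                A,
            )
            self.network_ = None
        self.MS_, self.DS_ = build_similarity_networks(
            network,
            dags or {},
            semantic_params=SemanticParams(delta=self.delta),
            gip_params=GipParams(bandwidth_prime=self.bandwidth_prime),
            S_d=S_d,
        )
        self.scores_ = birw_predict(self.MS_, self.DS_, network.A, self._walk_params())
        self.n_features_in_ = network.A.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Return the fitted score matrix (the method scores the training graph)."""
        if not hasattr(self, "scores_"):
            raise AttributeError("MDBIRW instance is not fitted yet; call fit first")
        return self.scores_

    def fit_predict(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).scores_
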