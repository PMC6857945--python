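"""Cross-validation, ROC/PR metrics and per-disease ranking.

Evaluation follows the balanced design: held-out known associations are the
positives, and an equal number of never-associated pairs are drawn uniformly
at random as negatives. Scores come from models refit with the held-out cells
zeroed; by default the association-dependent similarities (GIP kernels and
the MISIM-style functional similarity) are recomputed per fold, while the
semantic similarity — which does not depend on the association matrix — is
computed once and reused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .birw import WalkParams, birw_predict
from .data import AssociationNetwork, DiseaseDAG
from .similarity import (
    GipParams,
    SemanticParams,
    build_similarity_networks,
    disease_semantic_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CvScheme",
    "ScoredPair",
    "EvalReport",
    "confusion_rates",
    "roc_auc",
    "pr_aupr",
    "sample_negatives",
    "run_cv",
    "rank_metabolites",
]


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation layout: LOOCV or seeded k-fold over known associations."""

    mode: str = "loocv"
    k: int = 5
    seed: int = 0
    recompute_similarity: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("loocv", "kfold"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError(f"kfold needs k >= 2, got {self.k}")


@dataclass(frozen=True)
class ScoredPair:
    metabolite: str
    disease: str
    score: float
    label: int  # 1 = held-out positive, 0 = sampled negative


@dataclass
class EvalReport:
    """Aggregated CV result: scored pairs, ROC/PR points, AUC and AUPR."""

    pairs: list[ScoredPair]
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    aupr: float
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "n_pairs": len(self.pairs),
            "roc": {"fpr": self.fpr.tolist(), "tpr": self.tpr.tolist()},
            "pr": {"recall": self.recall.tolist(), "precision": self.precision.tolist()},
            "per_fold": self.per_fold,
        }


def confusion_rates(pairs: list[ScoredPair], threshold: float) -> tuple[float, float, float, float]:
    """TPR, FPR, precision and recall at a score threshold (score >= threshold).

    Recall is identical to TPR by definition. Raises if there are no positive
    pairs (the rates are undefined rather than zero).
    """
    if not pairs:
        raise ValueError("no scored pairs")
    labels = np.array([p.label for p in pairs])
    preds = np.array([p.score for p in pairs]) >= threshold
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0:
        raise ValueError("no positive pairs: TPR/recall undefined")
    tp = int((preds & (labels == 1)).sum())
    fp = int((preds & (labels == 0)).sum())
    tpr = tp / n_pos
    fpr = fp / n_neg if n_neg else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return tpr, fpr, precision, tpr


def _split_scores(pairs: list[ScoredPair]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.array([p.label for p in pairs])
    scores = np.array([p.score for p in pairs], dtype=float)
    if labels.min() == labels.max():
        raise ValueError("need both positive and negative pairs")
    return labels, scores


def roc_auc(pairs: list[ScoredPair]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (thresholds descending) and trapezoid AUC.

    The trapezoid AUC over the ROC steps equals the Mann–Whitney probability
    that a random positive outscores a random negative, ties counted half.
    """
    labels, scores = _split_scores(pairs)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def pr_aupr(pairs: list[ScoredPair]) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision–recall points and the trapezoid area over recall."""
    labels, scores = _split_scores(pairs)
    precision, recall, _ = precision_recall_curve(labels, scores)
    # arrays are ordered by increasing threshold (recall decreasing along the
    # curve); reverse to integrate along the curve with recall ascending
    aupr = float(np.trapezoid(precision[::-1], recall[::-1]))
    return precision, recall, aupr


def sample_negatives(
    network: AssociationNetwork, n: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw n distinct (metabolite, disease) index pairs with no known association.

    Negatives are drawn from cells that are zero anywhere in the full matrix,
    never from held-out positives.
    """
    zero_rows, zero_cols = np.nonzero(network.A == 0)
    n_zero = zero_rows.size
    if n > n_zero:
        raise ValueError(f"requested {n} negatives but only {n_zero} zero cells exist")
    chosen = rng.choice(n_zero, size=n, replace=False)
    return list(zip(zero_rows[chosen].tolist(), zero_cols[chosen].tolist()))


def _make_folds(
    n_pos: int, scheme: CvScheme, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n_pos)
    if scheme.mode == "loocv" or scheme.k >= n_pos:
        return [np.array([i]) for i in order]
    return list(np.array_split(order, scheme.k))


def run_cv(
    network: AssociationNetwork,
    dags: dict[str, DiseaseDAG],
    params: WalkParams = WalkParams(),
    scheme: CvScheme = CvScheme(),
    semantic_params: SemanticParams = SemanticParams(),
    gip_params: GipParams = GipParams(),
) -> EvalReport:
    """Cross-validate the predictor over the known associations.

    Each fold's positives are zeroed in the training matrix; the model is
    refit and the held-out cells are read from the resulting score matrix.
    An equal number of never-associated pairs is sampled once (with the
    scheme's seed) and partitioned over the folds so that every fold
    contributes a balanced set of scored pairs.
    """
    positives = network.positive_pairs()
    n_pos = len(positives)
    if n_pos < 2:
        raise ValueError("need at least 2 known associations for cross-validation")
    rng = np.random.default_rng(scheme.seed)
    folds = _make_folds(n_pos, scheme, rng)
    negatives = sample_negatives(network, n_pos, rng)
    neg_order = rng.permutation(n_pos)

    S_d = disease_semantic_similarity(dags, network.diseases.ids, semantic_params)
    if not scheme.recompute_similarity:
        MS_full, DS_full = build_similarity_networks(
            network, dags, semantic_params, gip_params, S_d=S_d
        )

    met_ids = network.metabolites.ids
    dis_ids = network.diseases.ids
    all_pairs: list[ScoredPair] = []
    per_fold: list[dict] = []
    neg_start = 0
    for fold_idx, fold in enumerate(folds):
        if fold.size == 0:
            logger.warning("fold %d has no positives; skipped", fold_idx)
            continue
        A_train = network.A.copy()
        held_out = [positives[i] for i in fold]
        for i, j in held_out:
            A_train[i, j] = 0.0
        train_net = AssociationNetwork(network.metabolites, network.diseases, A_train)
        if scheme.recompute_similarity:
            MS, DS = build_similarity_networks(
                train_net, dags, semantic_params, gip_params, S_d=S_d
            )
        else:
            MS, DS = MS_full, DS_full
        R = birw_predict(MS, DS, A_train, params)
        fold_negs = [negatives[neg_order[k]] for k in range(neg_start, neg_start + fold.size)]
        neg_start += fold.size
        fold_pairs = [
            ScoredPair(met_ids[i], dis_ids[j], float(R[i, j]), 1) for i, j in held_out
        ] + [ScoredPair(met_ids[i], dis_ids[j], float(R[i, j]), 0) for i, j in fold_negs]
        all_pairs.extend(fold_pairs)
        per_fold.append(
            {"fold": fold_idx, "n_pos": int(fold.size), "n_neg": len(fold_negs)}
        )

    fpr, tpr, auc_val = roc_auc(all_pairs)
    precision, recall, aupr_val = pr_aupr(all_pairs)
    return EvalReport(
        pairs=all_pairs,
        fpr=fpr,
        tpr=tpr,
        precision=precision,
        recall=recall,
        auc=auc_val,
        aupr=aupr_val,
        per_fold=per_fold,
    )


def rank_metabolites(
    network: AssociationNetwork,
    dags: dict[str, DiseaseDAG],
    params: WalkParams,
    disease: str,
    top_k: int = 10,
    semantic_params: SemanticParams = SemanticParams(),
    gip_params: GipParams = GipParams(),
) -> list[ScoredPair]:
    """Blind ranking of metabolites for one disease.

    All of the disease's known associations are removed from the training
    matrix, similarities are recomputed, and the metabolites are ranked by
    their predicted score for that disease (ties broken by registry order).
    The returned pairs are labelled by whether they were known in the original
    network, enabling recovery checks.
    """
    if disease not in network.diseases:
        raise ValueError(f"unknown disease {disease!r}")
    j = network.diseases.index[disease]
    A_train = network.A.copy()
    A_train[:, j] = 0.0
    train_net = AssociationNetwork(network.metabolites, network.diseases, A_train)
    MS, DS = build_similarity_networks(train_net, dags, semantic_params, gip_params)
    R = birw_predict(MS, DS, A_train, params)
    order = np.argsort(-R[:, j], kind="stable")
    met_ids = network.metabolites.ids
    return [
        ScoredPair(met_ids[i], disease, float(R[i, j]), int(network.A[i, j]))
        for i in order[:top_k]
    ]
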