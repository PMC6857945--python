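"""Bi-random walks on the heterogeneous metabolite–disease network.

Two coupled fixed-step propagations share the rescaled association matrix A0
as restart distribution:

    left  (metabolite side):  RM_t = α · MS' · RM_{t-1} + (1 − α) · A0
    right (disease side):     RD_t = α · RD_{t-1} · DS' + (1 − α) · A0

MS' and DS' are the normalized integrated similarity networks; the two walks
are bounded by independent step counts l and r, and after every iteration the
score matrix R averages whichever walks actually executed. Unequal l and r
let the walker exploit one sub-network's structure more deeply than the
other's.

Flag semantics: a walk contributes to the average only in iterations where it
executed (its bound not yet exhausted). A strict mode that always averages
both matrices — including the stale one once a bound is exceeded — is kept
behind ``strict_pseudocode=True`` for comparison; under it, unequal bounds
only freeze one matrix rather than removing it from the average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WalkParams",
    "WalkState",
    "normalize_similarity",
    "initialize_walk",
    "birw_step",
    "birw_predict",
]


@dataclass(frozen=True)
class WalkParams:
    """Decay factor α and the per-side step bounds l (metabolite) and r (disease)."""

    alpha: float = 0.3
    l: int = 3
    r: int = 3
    normalization: str = "laplacian"
    strict_pseudocode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.l < 1 or self.r < 1:
            raise ValueError(f"step bounds l, r must be >= 1, got l={self.l}, r={self.r}")
        if self.normalization not in ("laplacian", "row"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class WalkState:
    """Propagation matrices of both walks plus the combined score matrix."""

    RM: np.ndarray
    RD: np.ndarray
    R: np.ndarray
    A0: np.ndarray
    t: int = 0
    flagm: int = 0
    flagd: int = 0


def normalize_similarity(S: SimilarityMatrix, method: str = "laplacian") -> SimilarityMatrix:
    """Normalize a similarity matrix for propagation.

    ``laplacian``: S'(i,j) = S(i,j) / sqrt(deg_i · deg_j) with deg the row
    sums (symmetric normalization). ``row``: each row divided by its sum
    (row-stochastic). Zero-degree rows are left as zeros under both methods.
    """
    V = S.values
    if V.min() < 0:
        raise ValueError("cannot normalize a matrix with negative entries")
    deg = V.sum(axis=1)
    safe = np.where(deg > 0, deg, 1.0)
    if method == "laplacian":
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(safe), 0.0)
        out = V * inv_sqrt[:, None] * inv_sqrt[None, :]
    elif method == "row":
        out = V * np.where(deg > 0, 1.0 / safe, 0.0)[:, None]
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return SimilarityMatrix(S.kind, "normalized", out)


def initialize_walk(A: np.ndarray) -> WalkState:
    """Rescale A by its global element sum and seed both walks with it."""
    A = np.asarray(A, dtype=float)
    total = A.sum()
    if total <= 0:
        raise ValueError("association matrix has no known associations")
    A0 = A / total
    return WalkState(RM=A0.copy(), RD=A0.copy(), R=A0.copy(), A0=A0)


def birw_step(
    state: WalkState,
    MS_norm: np.ndarray,
    DS_norm: np.ndarray,
    params: WalkParams,
) -> WalkState:
    """Advance both walks by one iteration (in place) and recombine R.

    At iteration t+1 the metabolite-side walk runs iff t+1 <= l and the
    disease-side walk iff t+1 <= r; R is the average of the walks that ran.
    In strict mode both flags stay raised, so stale matrices keep averaging in.
    """
    t_next = state.t + 1
    if params.strict_pseudocode:
        state.flagm = state.flagd = 1
    else:
        state.flagm = state.flagd = 0
    alpha = params.alpha
    ran = False
    if t_next <= params.l:
        state.RM = alpha * (MS_norm @ state.RM) + (1.0 - alpha) * state.A0
        state.flagm = 1
        ran = True
    if t_next <= params.r:
        state.RD = alpha * (state.RD @ DS_norm) + (1.0 - alpha) * state.A0
        state.flagd = 1
        ran = True
    if state.flagm + state.flagd == 0:
        warnings.warn("both walk bounds exhausted; step is a no-op", stacklevel=2)
        return state
    if not ran and params.strict_pseudocode:
        warnings.warn("both walk bounds exhausted; averaging stale matrices", stacklevel=2)
    state.R = (state.flagm * state.RM + state.flagd * state.RD) / (state.flagm + state.flagd)
    state.t = t_next
    return state


def birw_predict(
    MS: SimilarityMatrix | np.ndarray,
    DS: SimilarityMatrix | np.ndarray,
    A: np.ndarray,
    params: WalkParams = WalkParams(),
    normalized: bool = False,
) -> np.ndarray:
    """Run the full bi-random-walks iteration and return the score matrix R.

    ``MS`` (m×m) and ``DS`` (n×n) are the integrated similarity networks;
    they are normalized here unless ``normalized`` is set. The walk runs
    max(l, r) iterations from R_0 = A / sum(A). Deterministic: no randomness
    is involved anywhere in the propagation.
    """
    MS_mat = MS if isinstance(MS, SimilarityMatrix) else SimilarityMatrix("metabolite", "integrated", MS)
    DS_mat = DS if isinstance(DS, SimilarityMatrix) else SimilarityMatrix("disease", "integrated", DS)
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    if MS_mat.n != m or DS_mat.n != n:
        raise ValueError(
            f"shape mismatch: A is {A.shape}, MS {MS_mat.values.shape}, DS {DS_mat.values.shape}"
        )
    if normalized:
        MS_n, DS_n = MS_mat.values, DS_mat.values
    else:
        MS_n = normalize_similarity(MS_mat, params.normalization).values
        DS_n = normalize_similarity(DS_mat, params.normalization).values
    state = initialize_walk(A)
    for _ in range(max(params.l, params.r)):
        birw_step(state, MS_n, DS_n, params)
    return state.R
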