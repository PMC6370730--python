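"""Similarity kernel fusion: cross-diffusion of per-view kernels.

Each view contributes a column-stochastic kernel ``P_l`` and a row-stochastic
sparse diffusion operator ``S_l``. The fusion iteration propagates the other
views' states through each view's own neighborhood graph,

    P_l^{t+1} = alpha * S_l (mean_{r != l} P_r^t) S_l^T
                + (1 - alpha) * mean_{r != l} P_r^0,

so that ``alpha`` trades off diffused cross-view information against the
original (t = 0) cross-view average. After convergence the per-view states
are averaged into ``K_com`` and a mutual-k-nearest-neighbor weight mask with
entries in {0, 0.5, 1} suppresses non-reciprocated similarities, yielding the
final fused kernel ``K*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, zscore_normalize
from .kernels import (
    NeighborSets,
    SimilarityKernel,
    distance_to_similarity,
    knn_sets,
    normalize_P,
    pairwise_distance_kernel,
    sparsify_S,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FusionParams",
    "FusionResult",
    "default_neighborhood_size",
    "skf_iterate",
    "combine_kernels",
    "mutual_weight_matrix",
    "apply_weight",
    "skf",
]


def default_neighborhood_size(n_patients: int) -> int:
    """Neighborhood size heuristic: max(5, n/10), capped at n - 1."""
    return min(n_patients - 1, max(5, round(n_patients / 10)))


@dataclass
class FusionParams:
    """Tunable parameters of the fusion iteration.

    alpha : float in [0, 1]
        Diffusion weight. 0 keeps only the initial cross-view average;
        1 keeps only the diffused term.
    k : int or None
        Neighborhood size for the sparse kernels and the mutual mask.
        None selects ``default_neighborhood_size`` at run time.
    mu : float
        Bandwidth of the scaled exponential similarity kernel.
    max_iters, tol :
        The iteration stops when the largest per-view relative Frobenius
        change drops below ``tol``, or after ``max_iters`` sweeps.
    """

    alpha: float = 0.5
    k: int | None = None
    mu: float = 0.5
    max_iters: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FusionResult:
    """Output of :func:`skf`: the fused kernel plus convergence diagnostics."""

    fused: SimilarityKernel
    per_view_final: list[SimilarityKernel]
    iterations_run: int
    converged: bool
    history: list[float] = field(default_factory=list)


def _renormalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums = np.where(sums > 0, sums, 1.0)
    return m / sums


def skf_iterate(
    P_list: list[SimilarityKernel],
    S_list: list[SimilarityKernel],
    params: FusionParams,
) -> tuple[list[SimilarityKernel], int, bool, list[float]]:
    """Run the cross-diffusion recurrence until convergence.

    Updates are synchronous: every view's t+1 state is computed from the full
    t state before any is applied. Each updated ``P_l`` is column-renormalized
    to preserve the stochastic invariant that the initial normalization
    established. Returns ``(final P kernels, iterations run, converged,
    per-iteration relative-change history)``.
    """
    L = len(P_list)
    if L < 2 or len(S_list) != L:
        raise ValueError("need matching P and S lists with at least two views")
    ids = P_list[0].patient_ids
    n = len(ids)
    for kern in (*P_list, *S_list):
        if kern.patient_ids != ids:
            raise ValueError("all kernels must share one patient list and order")
        if kern.matrix.shape != (n, n):
            raise ValueError("kernel dimension mismatch")

    P0 = [p.matrix.copy() for p in P_list]
    S = [s.matrix for s in S_list]
    anchor_total = np.sum(P0, axis=0)
    anchors = [(anchor_total - P0[l]) / (L - 1) for l in range(L)]

    P = [p.copy() for p in P0]
    history: list[float] = []
    converged = False
    iterations = 0
    alpha = params.alpha
    for _ in range(params.max_iters):
        total = np.sum(P, axis=0)
        new_P = []
        for l in range(L):
            others = (total - P[l]) / (L - 1)
            updated = alpha * (S[l] @ others @ S[l].T) + (1 - alpha) * anchors[l]
            new_P.append(_renormalize_columns(updated))
        change = max(
            float(np.linalg.norm(new_P[l] - P[l]) / max(np.linalg.norm(P[l]), 1e-300))
            for l in range(L)
        )
        P = new_P
        iterations += 1
        history.append(change)
        if change < params.tol:
            converged = True
            break
    if not converged:
        logger.info("skf_iterate: no convergence after %d iterations (last change %.3g)",
                    iterations, history[-1])
    finals = [SimilarityKernel(p, ids, kind="normalized_P") for p in P]
    return finals, iterations, converged, history


def combine_kernels(P_list: list[SimilarityKernel]) -> SimilarityKernel:
    """Element-wise mean of the per-view kernels: K_com = (1/L) sum_l P_l."""
    if not P_list:
        raise ValueError("empty kernel list")
    ids = P_list[0].patient_ids
    mats = [p.matrix for p in P_list]
    if any(m.shape != mats[0].shape for m in mats):
        raise ValueError("kernel shape mismatch")
    return SimilarityKernel(np.mean(mats, axis=0), ids, kind="combined")


def mutual_weight_matrix(neighbors: NeighborSets) -> np.ndarray:
    """Mutual-kNN weight mask with entries in {0, 0.5, 1}.

    w_ij = 1 when i and j are reciprocal neighbors, 0.5 when only one lists
    the other, and 0 when neither does. The diagonal is always 1 because
    every patient belongs to its own neighbor set.
    """
    m = neighbors.mask()
    return 1.0 * (m & m.T) + 0.5 * (m ^ m.T)


def apply_weight(K_com: SimilarityKernel, w: np.ndarray) -> SimilarityKernel:
    """Apply the mutual-neighbor mask and symmetrize: K* = sym(w o K_com)."""
    if w.shape != K_com.matrix.shape:
        raise ValueError("weight matrix shape mismatch")
    masked = w * K_com.matrix
    fused = (masked + masked.T) / 2.0
    return SimilarityKernel(fused, K_com.patient_ids, kind="fused")


def skf(cohort: Cohort, params: FusionParams | None = None, normalize: bool = True) -> FusionResult:
    """Full fusion pipeline from a multi-view cohort to the fused kernel.

    Per view: z-score features, squared-Euclidean distances, locally-scaled
    exponential similarity, then the normalized (P) and sparse (S) kernels.
    The views are fused by :func:`skf_iterate`, averaged, and denoised with
    the mutual-neighbor mask (recomputed on the combined kernel, since that
    is the object being cleaned). Deterministic given the inputs and params.
    """
    params = params or FusionParams()
    n = cohort.n_patients
    k = params.k if params.k is not None else default_neighborhood_size(n)
    if not 1 <= k <= n - 1:
        raise ValueError(f"neighborhood size k={k} invalid for {n} patients")

    P_list: list[SimilarityKernel] = []
    S_list: list[SimilarityKernel] = []
    for view in cohort.views:
        v = zscore_normalize(view) if normalize else view
        D = pairwise_distance_kernel(v)
        nb_dist = knn_sets(D, k, largest=False)
        K = distance_to_similarity(D, nb_dist, mu=params.mu)
        P_list.append(normalize_P(K))
        S_list.append(sparsify_S(K, knn_sets(K, k, largest=True)))

    finals, iterations, converged, history = skf_iterate(P_list, S_list, params)
    K_com = combine_kernels(finals)
    nb_com = knn_sets(K_com, k, largest=True)
    w = mutual_weight_matrix(nb_com)
    fused = apply_weight(K_com, w)
    return FusionResult(fused, finals, iterations, converged, history)
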