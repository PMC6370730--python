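"""Per-view patient similarity kernels and their normalized / sparse forms.

A view is turned into a patient x patient kernel in two steps: squared
Euclidean distances between patient profiles, then a locally-scaled
exponential similarity (the scaled exponential kernel of the similarity
network fusion lineage). Two derived operators feed the fusion iteration:

* ``P`` — the column-stochastic normalized kernel, and
* ``S`` — the row-stochastic sparse kernel supported on each patient's
  k nearest neighbors plus itself, which acts as the diffusion operator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionView

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityKernel",
    "NeighborSets",
    "pairwise_distance_kernel",
    "distance_to_similarity",
    "knn_sets",
    "normalize_P",
    "sparsify_S",
]

_KINDS = ("raw", "normalized_P", "sparse_S", "combined", "fused")


@dataclass
class SimilarityKernel:
    """A square patient x patient matrix tied to an ordered patient list.

    ``kind`` records which invariants hold: ``raw`` kernels are symmetric
    (this covers both distance and similarity matrices), ``normalized_P``
    kernels are column-stochastic, ``sparse_S`` kernels are row-stochastic
    with support restricted to neighbor sets, and ``fused`` is the final
    integrated kernel.
    """

    matrix: np.ndarray
    patient_ids: list[str]
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        n = len(self.patient_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"kernel shape {self.matrix.shape} does not match {n} patients")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("kernel contains non-finite entries")
        if self.matrix.min() < 0:
            raise ValueError("kernel contains negative entries")
        if self.kind in ("raw", "fused"):
            if np.abs(self.matrix - self.matrix.T).max() > 1e-10:
                raise ValueError(f"{self.kind} kernel must be symmetric")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class NeighborSets:
    """For each patient ``i``, the index set ``N_i`` of its k nearest
    neighbors plus ``i`` itself, stored as a sorted ``(n, k+1)`` array."""

    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        n = self.indices.shape[0]
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.indices.shape != (n, self.k + 1):
            raise ValueError(f"expected shape ({n}, {self.k + 1}), got {self.indices.shape}")
        rows = np.arange(n)
        if not (self.indices == rows[:, None]).any(axis=1).all():
            raise ValueError("every N_i must contain i itself")

    @property
    def n_patients(self) -> int:
        return self.indices.shape[0]

    def mask(self) -> np.ndarray:
        """Boolean (n, n) matrix with ``mask[i, j]`` true iff ``j in N_i``."""
        n = self.n_patients
        m = np.zeros((n, n), dtype=bool)
        m[np.arange(n)[:, None], self.indices] = True
        return m


def pairwise_distance_kernel(view: ExpressionView) -> SimilarityKernel:
    """Squared Euclidean distances D_ij = (e_i - e_j)^T (e_i - e_j).

    ``view`` is expected to be z-score normalized so every feature
    contributes on a comparable scale. The result is symmetric with a zero
    diagonal; it is a *distance* matrix and must be converted with
    :func:`distance_to_similarity` before normalization.
    """
    d = squareform(pdist(view.values, metric="sqeuclidean"))
    return SimilarityKernel(d, view.patient_ids, kind="raw")


def knn_sets(kernel: SimilarityKernel, k: int, largest: bool = True) -> NeighborSets:
    """Pick each patient's k nearest neighbors from a kernel row.

    ``largest=True`` reads the kernel as a similarity (keep the k largest
    off-diagonal entries); ``largest=False`` reads it as a distance (keep the
    smallest). Ties are broken by ascending patient index so that neighbor
    sets are reproducible across platforms.
    """
    n = kernel.n_patients
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    scores = kernel.matrix.copy()
    fill = -np.inf if largest else np.inf
    np.fill_diagonal(scores, fill)
    if largest:
        scores = -scores
    # stable sort => ties resolved toward the smaller index
    order = np.argsort(scores, axis=1, kind="stable")[:, :k]
    sets = np.sort(np.column_stack([np.arange(n), order]), axis=1)
    return NeighborSets(sets, k)


def distance_to_similarity(
    distances: SimilarityKernel,
    neighbors: NeighborSets,
    mu: float = 0.5,
) -> SimilarityKernel:
    """Convert squared distances to a locally-scaled exponential similarity.

    K_ij = exp(-D_ij / (mu * eps_ij)) with the local scale

        eps_ij = (m_i + m_j + D_ij) / 3,

    where m_i is the mean squared distance from patient i to its k nearest
    neighbors. Keeping eps on the same (squared) scale as the numerator
    makes the exponent dimensionless and invariant to the number of
    features, so the kernel does not collapse toward the identity as views
    grow wider. ``mu`` controls the bandwidth; values around 0.3-0.8 are
    sensible. Coincident neighborhoods (eps = 0) are floored at 1e-12 so
    the kernel stays defined; D_ii = 0 always maps to K_ii = 1.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    d = distances.matrix
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance kernel must have a zero diagonal")
    n = distances.n_patients
    neigh = neighbors.indices
    # mean local squared distance over N_i \ {i}
    rows = np.repeat(np.arange(n), neigh.shape[1])
    vals = d[rows, neigh.ravel()].reshape(n, -1)
    local_mean = vals.sum(axis=1) / neighbors.k  # self contributes 0
    eps = (local_mean[:, None] + local_mean[None, :] + d) / 3.0
    floored = eps < 1e-12
    if floored.any():
        logger.info("distance_to_similarity: floored %d zero local scales", int(floored.sum()))
        eps = np.maximum(eps, 1e-12)
    sim = np.exp(-d / (mu * eps))
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityKernel(sim, distances.patient_ids, kind="raw")


def normalize_P(kernel: SimilarityKernel) -> SimilarityKernel:
    """Column-stochastic normalization: P_ij = K_ij / sum_k K_kj."""
    col_sums = kernel.matrix.sum(axis=0)
    zero = col_sums <= 0
    if zero.any():
        bad = [kernel.patient_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero column sum for patients {bad}")
    return SimilarityKernel(
        kernel.matrix / col_sums, kernel.patient_ids, kind="normalized_P"
    )


def sparsify_S(kernel: SimilarityKernel, neighbors: NeighborSets) -> SimilarityKernel:
    """Row-stochastic sparse kernel supported on each patient's neighbor set.

    S_ij = K_ij / sum_{k in N_i} K_ik for j in N_i, else 0. Entries outside
    the k-nearest-neighbor sets are zeroed, discarding weak similarities
    before diffusion.
    """
    if neighbors.n_patients != kernel.n_patients:
        raise ValueError("neighbor sets do not match kernel size")
    mask = neighbors.mask()
    masked = np.where(mask, kernel.matrix, 0.0)
    row_sums = masked.sum(axis=1)
    zero = row_sums <= 0
    if zero.any():
        bad = [kernel.patient_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero neighborhood sum for patients {bad}")
    return SimilarityKernel(
        masked / row_sums[:, None], kernel.patient_ids, kind="sparse_S"
    )
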