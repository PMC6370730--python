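"""Normalized-cut spectral clustering of the fused patient kernel.

Follows the Ng-Jordan-Weiss recipe: form the symmetric normalized Laplacian
L+ = I - D^{-1/2} K* D^{-1/2}, embed patients with the eigenvectors of the C
smallest eigenvalues, row-normalize the embedding, and discretize with
k-means. The relaxed objective min Trace(Q^T L+ Q) subject to Q^T Q = I is
attained exactly by those eigenvectors; k-means rounds the relaxation back
to a hard partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from .io import SurvivalTable
from .kernels import SimilarityKernel

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "normalized_laplacian",
    "spectral_embed",
    "cluster_embedding",
    "spectral_cluster",
    "scan_clusters",
]


@dataclass
class ClusterAssignment:
    """A patient partition into C clusters plus the spectral embedding used."""

    labels: np.ndarray
    n_clusters: int
    patient_ids: list[str]
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.patient_ids),):
            raise ValueError("labels length must match patient_ids")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.n_clusters:
            raise ValueError(f"labels outside [0, {self.n_clusters})")
        if len(present) != self.n_clusters:
            raise ValueError("every cluster must be nonempty")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_ids, "cluster": self.labels})


def normalized_laplacian(kernel: SimilarityKernel) -> np.ndarray:
    """Symmetric normalized Laplacian L+ = I - D^{-1/2} K* D^{-1/2}.

    D is the diagonal degree matrix of row sums of the (symmetric,
    nonnegative) fused kernel. L+ is positive semidefinite with eigenvalues
    in [0, 2]; a zero-degree patient makes the normalization undefined and is
    reported as an error.
    """
    K = kernel.matrix
    if np.abs(K - K.T).max() > 1e-8:
        raise ValueError("kernel must be symmetric")
    deg = K.sum(axis=1)
    zero = deg <= 0
    if zero.any():
        bad = [kernel.patient_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero similarity degree for patients {bad}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    lap = -K * inv_sqrt[:, None] * inv_sqrt[None, :]
    lap[np.diag_indices_from(lap)] += 1.0
    return (lap + lap.T) / 2.0


def spectral_embed(laplacian: np.ndarray, n_clusters: int) -> np.ndarray:
    """Orthonormal embedding from the C smallest Laplacian eigenvectors.

    The returned Q minimizes Trace(Q^T L+ Q) subject to Q^T Q = I, so the
    trace at Q equals the sum of the C smallest eigenvalues. Each
    eigenvector's sign is fixed so its largest-magnitude entry is positive,
    making the embedding reproducible across eigensolvers. Row normalization
    (the Ng-Jordan-Weiss step before k-means) is applied later, in
    :func:`cluster_embedding`, so that the orthonormality contract holds
    here.
    """
    n = laplacian.shape[0]
    if not 2 <= n_clusters <= n - 1:
        raise ValueError(f"number of clusters must be in [2, {n - 1}], got {n_clusters}")
    _, vecs = scipy.linalg.eigh(laplacian, subset_by_index=[0, n_clusters - 1])
    # deterministic sign: largest-|entry| coordinate positive
    anchor = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[anchor, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _normalize_rows(embedding: np.ndarray) -> np.ndarray:
    """Scale embedding rows to unit length; zero rows are left at zero."""
    norms = np.linalg.norm(embedding, axis=1)
    zero_rows = norms == 0
    if zero_rows.any():
        logger.info("embedding: %d zero rows left as-is", int(zero_rows.sum()))
    norms[zero_rows] = 1.0
    return embedding / norms[:, None]


def cluster_embedding(
    embedding: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    patient_ids: list[str] | None = None,
    n_init: int = 10,
    row_normalize: bool = True,
) -> ClusterAssignment:
    """k-means on the row-normalized embedding, deterministic for a seed.

    Rows are first scaled to unit length (the Ng-Jordan-Weiss step), the
    best of ``n_init`` k-means restarts (by inertia) is kept, and clusters
    are relabeled by descending size (ties by first occurrence) so that
    label values are stable and comparable across runs. Set
    ``row_normalize=False`` to cluster the raw coordinates.
    """
    n = embedding.shape[0]
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    if row_normalize:
        embedding = _normalize_rows(embedding)
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    raw = km.fit_predict(embedding)
    if len(np.unique(raw)) < n_clusters:
        # rare: retry with more, differently-seeded restarts
        km = KMeans(n_clusters=n_clusters, n_init=4 * n_init, random_state=seed + 1)
        raw = km.fit_predict(embedding)
        if len(np.unique(raw)) < n_clusters:
            raise RuntimeError(f"k-means could not fill {n_clusters} clusters")
    sizes = np.bincount(raw, minlength=n_clusters)
    first_seen = np.array([np.argmax(raw == c) for c in range(n_clusters)])
    order = sorted(range(n_clusters), key=lambda c: (-sizes[c], first_seen[c]))
    relabel = np.empty(n_clusters, dtype=int)
    relabel[order] = np.arange(n_clusters)
    return ClusterAssignment(relabel[raw], n_clusters, patient_ids, embedding)


def spectral_cluster(
    kernel: SimilarityKernel, n_clusters: int, seed: int = 0
) -> ClusterAssignment:
    """Partition patients from the fused kernel into ``n_clusters`` groups."""
    lap = normalized_laplacian(kernel)
    emb = spectral_embed(lap, n_clusters)
    return cluster_embedding(emb, n_clusters, seed=seed, patient_ids=kernel.patient_ids)


def scan_clusters(
    kernel: SimilarityKernel,
    c_range,
    survival: SurvivalTable,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster at every C in ``c_range`` and score survival separation.

    Returns one row per candidate C with the log-rank chi-square, p-value and
    -log10(p), the curve used to pick the number of subtypes.
    """
    from .survival import logrank_test, neglog10_p

    if survival.patient_ids != kernel.patient_ids:
        raise ValueError("survival table and kernel patient lists differ")
    rows = []
    for c in c_range:
        assignment = spectral_cluster(kernel, int(c), seed=seed)
        res = logrank_test(survival, assignment)
        rows.append(
            {
                "n_clusters": int(c),
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "neg_log10_p": neglog10_p(res.p_value),
            }
        )
    return pd.DataFrame(rows)
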