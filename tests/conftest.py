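import numpy as np
import pytest

from skfuse.io import Cohort, ExpressionView
from skfuse.kernels import SimilarityKernel


def ids(n, prefix="P"):
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def make_view(values, name="view", prefix="P"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionView(values, ids(n, prefix), [f"f{j + 1}" for j in range(m)], name)


def make_kernel(matrix, kind="raw"):
    matrix = np.asarray(matrix, dtype=float)
    return SimilarityKernel(matrix, ids(matrix.shape[0]), kind=kind)


def random_similarity(rng, n):
    """A random symmetric nonnegative kernel with unit diagonal."""
    a = rng.uniform(0.05, 1.0, (n, n))
    k = (a + a.T) / 2
    np.fill_diagonal(k, 1.0)
    return make_kernel(k)


def two_block_kernel(rng, n, split=None, within=(0.8, 1.0), between=(0.0, 0.2)):
    """A symmetric kernel with two planted diagonal blocks; returns labels too."""
    split = split if split is not None else n // 2
    labels = np.array([0] * split + [1] * (n - split))
    same = labels[:, None] == labels[None, :]
    lo_w, hi_w = within
    lo_b, hi_b = between
    a = np.where(same, rng.uniform(lo_w, hi_w, (n, n)), rng.uniform(lo_b, hi_b, (n, n)))
    k = (a + a.T) / 2
    np.fill_diagonal(k, 1.0)
    return make_kernel(k, kind="fused"), labels


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_cohort(rng):
    """A 12-patient, 3-view cohort with two planted clusters of 6."""
    labels = np.repeat([0, 1], 6)
    views = []
    for v in range(3):
        shift = np.where(labels[:, None] == 0, 0.0, 5.0)
        values = shift + rng.normal(0, 1, (12, 8))
        views.append(make_view(values, name=f"view{v + 1}"))
    return Cohort(views), labels
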