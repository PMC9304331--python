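"""Gaussian-kernel genomic similarity matrices.

The kernel between genotypes :math:`x_i` and :math:`x_{i'}` over *p* loci is

.. math:: GK(x_i, x_{i'}) = \\exp\\{-(h/p) \\sum_k (x_{ik} - x_{i'k})^2\\}

with bandwidth ``h`` (1 for the single-kernel SM-GK model).  The kernel-
averaging family uses bandwidths 15, 5 and 1 on squared distances divided by
``M``, the median squared Euclidean distance across genotypes, so that the
median pair sits at distance 1 and the three kernels span local to global
similarity.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genodata import GenotypeMatrix

__all__ = ["median_sq_distance", "gaussian_kernel", "kernel_averaging_bandwidths"]

#: bandwidths of the kernel-averaging (RKHS-KA) family, applied to M-scaled distances
KERNEL_AVERAGING_BANDWIDTHS = (15.0, 5.0, 1.0)


def _as_array(g) -> np.ndarray:
    if isinstance(g, GenotypeMatrix):
        return g.values
    return np.asarray(g, dtype=float)


def _sq_distances(x: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances, computed via the Gram matrix."""
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def median_sq_distance(g) -> float:
    """Median squared Euclidean distance over all unordered genotype pairs."""
    x = _as_array(g)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two individuals to compute pairwise distances")
    if x.shape[0] * x.shape[1] > 5_000_000:
        d2 = squareform(_sq_distances(x), checks=False)
    else:
        d2 = pdist(x, metric="sqeuclidean")
    return float(np.median(d2))


def gaussian_kernel(g, h: float = 1.0, scale: str | float | None = None) -> np.ndarray:
    """Gaussian kernel matrix K[i,i'] = exp(-(h/p) * d2(i,i') / s).

    ``scale=None`` uses raw squared distances (the SM-GK convention with
    h = 1); ``scale="median"`` divides them by the median squared distance M
    (the kernel-averaging convention); a float fixes s explicitly.
    """
    if h <= 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    x = _as_array(g)
    if np.isnan(x).any():
        raise ValueError("genotype matrix contains missing values; impute first")
    p = x.shape[1]
    d2 = _sq_distances(x)
    if scale is None:
        s = 1.0
    elif scale == "median":
        s = median_sq_distance(x)
        if s <= 0:
            raise ValueError("median squared distance is zero; genotypes degenerate")
    else:
        s = float(scale)
        if s <= 0:
            raise ValueError("scale must be positive")
    K = np.exp(-(h / p) * d2 / s)
    np.fill_diagonal(K, 1.0)
    return K


def kernel_averaging_bandwidths(g) -> list[np.ndarray]:
    """The three M-scaled kernels (h = 15, 5, 1) used by the RKHS-KA model."""
    x = _as_array(g)
    M = median_sq_distance(x)
    return [gaussian_kernel(x, h=h, scale=M) for h in KERNEL_AVERAGING_BANDWIDTHS]


def check_kernel(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate symmetry and positive semidefiniteness of a kernel matrix."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"kernel is not positive semidefinite (min eigenvalue {w.min():.3g})")
    return K
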