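"""Gaussian interaction profile (GIP) kernel similarity.

An entity's interaction profile is its binary association vector: a
disease's row of the adjacency matrix, a microbe's column. Two entities are
similar when their profiles are close in squared Euclidean distance -- which
for binary vectors is just the Hamming distance -- under a Gaussian kernel

    K(i, j) = exp(-gamma * ||IP_i - IP_j||^2)

with bandwidth gamma normalised by the mean squared profile norm:

    gamma = gamma' / (mean_i ||IP_i||^2)

so that the kernel's length scale tracks how densely annotated the network
is. ``gamma' = 1`` is the conventional default on both axes.

Entities with empty (all-zero) profiles are allowed: they contribute zero to
the bandwidth average but still count in its denominator, and their distance
to any other profile is that profile's number of ones. Only a fully zero
matrix is rejected, because then the bandwidth itself is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationNetwork
from .exceptions import DegenerateNetworkError

__all__ = [
    "KernelSimilarityMatrix",
    "gip_bandwidth",
    "gip_kernel",
    "disease_kernel",
    "microbe_kernel",
]


@dataclass(frozen=True)
class KernelSimilarityMatrix:
    """Square symmetric GIP similarity matrix with its bandwidth record.

    Attributes
    ----------
    K
        ``(n, n)`` similarity matrix; symmetric, unit diagonal, entries in
        ``(0, 1]``.
    axis
        ``"disease"`` or ``"microbe"``, recording which profiles were used.
    gamma_prime
        The raw bandwidth parameter before normalisation.
    gamma
        The normalised bandwidth actually used in the exponent.
    """

    K: np.ndarray
    axis: str
    gamma_prime: float
    gamma: float

    def __post_init__(self) -> None:
        if self.axis not in ("disease", "microbe"):
            raise ValueError("axis must be 'disease' or 'microbe'")
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        K = K.copy()
        K.setflags(write=False)
        object.__setattr__(self, "K", K)

    @property
    def n(self) -> int:
        return self.K.shape[0]


def _as_profile_matrix(profiles: np.ndarray) -> np.ndarray:
    P = np.asarray(profiles)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix (one profile per row)")
    if not np.isin(P, (0, 1)).all():
        raise ValueError("profiles must be binary (0/1)")
    return P.astype(np.int64)


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Normalised kernel bandwidth ``gamma' / mean_i ||IP_i||^2``.

    For binary profiles ``||IP_i||^2`` is the number of ones in profile
    ``i``, so the denominator is the average association count per entity.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    P = _as_profile_matrix(profiles)
    mean_sq_norm = P.sum() / P.shape[0]
    if mean_sq_norm == 0:
        raise DegenerateNetworkError(
            "all interaction profiles are empty: the kernel bandwidth is "
            "undefined for a network with no associations"
        )
    return float(gamma_prime) / float(mean_sq_norm)


def gip_kernel(
    profiles: np.ndarray, gamma: float, axis: str = "disease"
) -> KernelSimilarityMatrix:
    """Gaussian kernel over binary profiles at a given bandwidth.

    The squared distance ``||IP_i - IP_j||^2`` is computed in exact integer
    arithmetic (``s_i + s_j - 2 * IP_i . IP_j`` with ``s`` the row sums), so
    the matrix is exactly symmetric and the diagonal is exactly one before
    the single vectorised ``exp``.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    P = _as_profile_matrix(profiles)
    s = P.sum(axis=1)
    D = s[:, None] + s[None, :] - 2 * (P @ P.T)  # integer Hamming distances
    K = np.exp(-float(gamma) * D)
    return KernelSimilarityMatrix(
        K=K, axis=axis, gamma_prime=np.nan, gamma=float(gamma)
    )


def _kernel_from_profiles(
    profiles: np.ndarray, gamma_prime: float, axis: str
) -> KernelSimilarityMatrix:
    gamma = gip_bandwidth(profiles, gamma_prime)
    km = gip_kernel(profiles, gamma, axis=axis)
    return KernelSimilarityMatrix(
        K=km.K, axis=axis, gamma_prime=float(gamma_prime), gamma=gamma
    )


def disease_kernel(
    net: AssociationNetwork, gamma_prime_d: float = 1.0
) -> KernelSimilarityMatrix:
    """GIP similarity between diseases (profiles = rows of ``A``)."""
    return _kernel_from_profiles(net.A, gamma_prime_d, axis="disease")


def microbe_kernel(
    net: AssociationNetwork, gamma_prime_m: float = 1.0
) -> KernelSimilarityMatrix:
    """GIP similarity between microbes (profiles = columns of ``A``)."""
    return _kernel_from_profiles(net.A.T, gamma_prime_m, axis="microbe")
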