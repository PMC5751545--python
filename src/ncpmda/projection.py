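"""Network consistency projection (NCP) scoring.

A candidate pair (disease i, microbe j) is scored by projecting, in each of
the two similarity spaces, one network onto the other:

* disease space:  NCP_d(i, j) = KD_i . A_j / |A_j|   -- the disease-similarity
  vector of i projected onto microbe j's association column;
* microbe space:  NCP_m(i, j) = A_i . KM_j / |A_i|   -- disease i's
  association row projected onto the microbe-similarity vector of j;

and combining with a joint normalisation

    NCP(i, j) = (NCP_d(i, j) + NCP_m(i, j)) / (|KD_i| + |KM_j|)

where |.| is the Euclidean norm. The smaller the angle between the
similarity vector and the association vector, the larger the projection, so
pairs consistent with the network's neighbourhood structure score high. By
Cauchy-Schwarz NCP_d(i, j) <= |KD_i| and NCP_m(i, j) <= |KM_j|, hence
0 <= NCP <= 1 always. A projection onto (or of) an all-zero association
vector is defined as 0: a cold-start disease or microbe therefore draws its
whole score from the opposite space instead of being unscorable.

The score is closed form -- no iteration, no learned weights, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationNetwork
from .gip import KernelSimilarityMatrix, disease_kernel, microbe_kernel

__all__ = [
    "ScoreMatrix",
    "disease_space_projection",
    "microbe_space_projection",
    "combine_projections",
    "predict",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued disease x microbe NCP prediction scores in [0, 1]."""

    S: np.ndarray
    diseases: tuple[str, ...]
    microbes: tuple[str, ...]
    gamma_prime_d: float
    gamma_prime_m: float

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float).copy()
        if S.shape != (len(self.diseases), len(self.microbes)):
            raise ValueError("score matrix shape does not match label lists")
        S.setflags(write=False)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "diseases", tuple(self.diseases))
        object.__setattr__(self, "microbes", tuple(self.microbes))


def _check_kernel(kernel: KernelSimilarityMatrix, n: int, axis: str) -> None:
    if kernel.axis != axis:
        raise ValueError(f"expected a {axis}-axis kernel, got {kernel.axis!r}")
    if kernel.n != n:
        raise ValueError(
            f"kernel is {kernel.n}x{kernel.n} but the network has {n} "
            f"{axis}s"
        )


def disease_space_projection(
    KD: KernelSimilarityMatrix, net: AssociationNetwork
) -> np.ndarray:
    """Project disease similarity onto microbe association columns.

    Entry (i, j) is ``KD_i . A_j / |A_j|``; columns of microbes with no
    known association are zero.
    """
    _check_kernel(KD, net.nd, "disease")
    A = net.A.astype(float)
    col_norms = np.linalg.norm(A, axis=0)
    numer = KD.K @ A
    out = np.zeros_like(numer)
    nonzero = col_norms > 0
    out[:, nonzero] = numer[:, nonzero] / col_norms[nonzero]
    return out


def microbe_space_projection(
    net: AssociationNetwork, KM: KernelSimilarityMatrix
) -> np.ndarray:
    """Project disease association rows onto microbe similarity columns.

    Entry (i, j) is ``A_i . KM_j / |A_i|``; rows of diseases with no known
    association are zero.
    """
    _check_kernel(KM, net.nm, "microbe")
    A = net.A.astype(float)
    row_norms = np.linalg.norm(A, axis=1)
    numer = A @ KM.K
    out = np.zeros_like(numer)
    nonzero = row_norms > 0
    out[nonzero, :] = numer[nonzero, :] / row_norms[nonzero, None]
    return out


def combine_projections(
    ncp_d: np.ndarray,
    ncp_m: np.ndarray,
    KD: KernelSimilarityMatrix,
    KM: KernelSimilarityMatrix,
    net: AssociationNetwork,
) -> ScoreMatrix:
    """Combine the two projections into the final normalised score matrix.

    The denominator ``|KD_i| + |KM_j|`` is strictly positive (kernel
    diagonals are one), so no special casing is needed; entries where both
    projections vanish are exactly zero.
    """
    ncp_d = np.asarray(ncp_d, dtype=float)
    ncp_m = np.asarray(ncp_m, dtype=float)
    _check_kernel(KD, net.nd, "disease")
    _check_kernel(KM, net.nm, "microbe")
    if ncp_d.shape != (net.nd, net.nm) or ncp_m.shape != (net.nd, net.nm):
        raise ValueError("projection matrices must be nd x nm")
    row_norms = np.linalg.norm(KD.K, axis=1)
    col_norms = np.linalg.norm(KM.K, axis=0)
    S = (ncp_d + ncp_m) / (row_norms[:, None] + col_norms[None, :])
    return ScoreMatrix(
        S=S,
        diseases=net.diseases,
        microbes=net.microbes,
        gamma_prime_d=KD.gamma_prime,
        gamma_prime_m=KM.gamma_prime,
    )


def predict(
    net: AssociationNetwork,
    gamma_prime_d: float = 1.0,
    gamma_prime_m: float = 1.0,
) -> ScoreMatrix:
    """Score every disease-microbe pair of a network.

    Convenience pipeline: disease and microbe GIP kernels, the two space
    projections, and the combined normalised score. Deterministic; rejects a
    network with no associations at all.
    """
    KD = disease_kernel(net, gamma_prime_d)
    KM = microbe_kernel(net, gamma_prime_m)
    ncp_d = disease_space_projection(KD, net)
    ncp_m = microbe_space_projection(net, KM)
    return combine_projections(ncp_d, ncp_m, KD, KM, net)
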