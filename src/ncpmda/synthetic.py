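"""Synthetic bipartite association networks with planted block structure.

The prediction method rests on a guilt-by-association assumption: microbes
with similar functions share association patterns with phenotypically
similar diseases. The minimal generator embodying that assumption is a
bipartite stochastic block model -- diseases and microbes are assigned to
communities, and a pair is associated with probability ``p_in`` when their
communities match and ``p_out`` otherwise. Planted memberships are retained
as ground truth so recovery can be measured without any external database.

Defaults emulate the shape and sparsity of the curated human microbe-
disease association snapshot the method targets: 39 diseases x 292 microbes
at roughly 4% fill (about 450-530 associations), with 8 communities,
p_in = 0.30 and p_out = 0.01. Only the binary association layer is
simulated -- no abundances, no literature evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .associations import AssociationNetwork

__all__ = [
    "SyntheticTruth",
    "generate_block_network",
    "erdos_renyi_network",
    "hold_out_positives",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated network together with its planted ground truth.

    ``held_out`` lists positive pairs (as label tuples) that were removed
    from ``net.A`` but are true associations under the generator.
    """

    net: AssociationNetwork
    disease_blocks: np.ndarray
    microbe_blocks: np.ndarray
    p_in: float
    p_out: float
    seed: int
    held_out: tuple[tuple[str, str], ...] = ()


def _check_params(nd: int, nm: int, n_blocks: int, p_in: float, p_out: float) -> None:
    if not (1 <= n_blocks <= min(nd, nm)):
        raise ValueError("need nd, nm >= n_blocks >= 1")
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")


def generate_block_network(
    nd: int = 39,
    nm: int = 292,
    n_blocks: int = 8,
    p_in: float = 0.30,
    p_out: float = 0.01,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a planted-block bipartite association network.

    Entities are assigned to blocks round-robin (entity ``i`` to block
    ``i mod n_blocks``) so block sizes are reproducible, then each cell is
    an independent Bernoulli draw at ``p_in`` or ``p_out``. The draw is
    repeated (same generator stream) until the matrix is not all-zero, so
    the result is always a usable network; identical parameters and seed
    reproduce it bit for bit.
    """
    _check_params(nd, nm, n_blocks, p_in, p_out)
    rng = np.random.default_rng(seed)
    disease_blocks = np.arange(nd) % n_blocks
    microbe_blocks = np.arange(nm) % n_blocks
    prob = np.where(
        disease_blocks[:, None] == microbe_blocks[None, :], p_in, p_out
    )
    while True:
        A = (rng.random((nd, nm)) < prob).astype(np.int8)
        if A.any():
            break
    net = AssociationNetwork(
        diseases=tuple(f"disease_{i:03d}" for i in range(nd)),
        microbes=tuple(f"microbe_{j:03d}" for j in range(nm)),
        A=A,
    )
    return SyntheticTruth(
        net=net,
        disease_blocks=disease_blocks,
        microbe_blocks=microbe_blocks,
        p_in=p_in,
        p_out=p_out,
        seed=seed,
    )


def erdos_renyi_network(
    nd: int = 39, nm: int = 292, density: float = 0.04625, seed: int = 0
) -> SyntheticTruth:
    """Structureless control: one block, every cell at ``density``.

    Density-matched to the planted defaults
    (0.30 / 8 + 0.01 * 7 / 8 = 0.04625), so any ranking signal above chance
    on this network would indicate leakage rather than structure.
    """
    return generate_block_network(
        nd=nd, nm=nm, n_blocks=1, p_in=density, p_out=0.0, seed=seed
    )


def hold_out_positives(
    truth: SyntheticTruth, fraction: float, seed: int = 0
) -> SyntheticTruth:
    """Move a random fraction of the known positives into ``held_out``.

    At least one pair is removed and at least one must remain; the total
    number of positives is conserved between the matrix and the hold-out
    list. Used for recovery experiments: predict on the reduced network and
    check where the held-out true pairs rank.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be strictly between 0 and 1")
    A = np.array(truth.net.A, dtype=np.int8)
    positives = np.argwhere(A == 1)
    n_remove = max(1, int(round(fraction * len(positives))))
    if n_remove >= len(positives):
        raise ValueError(
            f"removing {n_remove} of {len(positives)} positives would leave "
            "an empty network"
        )
    rng = np.random.default_rng(seed)
    chosen = positives[rng.choice(len(positives), size=n_remove, replace=False)]
    A[chosen[:, 0], chosen[:, 1]] = 0
    held = tuple(
        (truth.net.diseases[i], truth.net.microbes[j]) for i, j in chosen
    )
    return replace(
        truth,
        net=truth.net.with_matrix(A),
        held_out=truth.held_out + held,
    )
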