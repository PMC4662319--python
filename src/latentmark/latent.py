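"""MCMC moves on the feasible set of latent-history frequencies.

The latent frequency vector ``x`` lives on the integer lattice slice
``{x >= 0 : A^T x = observed_counts}``.  Moves add a signed combination of
integer null-space basis vectors of ``A^T``.  The proposal below only ever
constructs nonnegative configurations (a signed basis vector is drawn
uniformly from the set that keeps the partially updated ``x`` nonnegative),
so no tuning is required; the Hastings ratio accounts for the differing
sizes of the admissible-move sets along the forward and reverse paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .histories import LatentMap

__all__ = ["SamplerConfig", "propose_move", "accept_move", "update_frequencies"]


@dataclass
class SamplerConfig:
    """Latent-move settings: ``maxnumbasis`` signed basis moves are combined
    per update (the number actually used is uniform on 1..maxnumbasis)."""

    maxnumbasis: int = 1

    def __post_init__(self) -> None:
        if self.maxnumbasis < 1:
            raise ValueError("maxnumbasis must be >= 1")


def _admissible(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Signed moves (row index, sign) keeping ``x + sign*b`` nonnegative.

    Returns an integer array of shape (m, 2); column 0 is the basis row,
    column 1 the sign.
    """
    ok_plus = np.all(x[None, :] + basis >= 0, axis=1)
    ok_minus = np.all(x[None, :] - basis >= 0, axis=1)
    rows = np.concatenate([np.flatnonzero(ok_plus), np.flatnonzero(ok_minus)])
    signs = np.concatenate(
        [np.ones(int(ok_plus.sum()), np.int64), -np.ones(int(ok_minus.sum()), np.int64)]
    )
    return np.stack([rows, signs], axis=1)


def propose_move(
    x: np.ndarray,
    lmap: LatentMap,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Propose ``x' = x + sum_k s_k b_{i_k}`` with ``x' >= 0`` by construction.

    Draws ``K ~ Uniform{1..maxnumbasis}`` and then ``K`` signed basis vectors
    sequentially, each uniform over the moves admissible at the partially
    updated state.  Returns ``(x_proposed, log_proposal_ratio)`` where the
    ratio is ``log q(x'->x) - log q(x->x')`` for the path-matched reverse
    move (same K, negated vectors in reverse order).  If no move is
    admissible, returns ``x`` unchanged with ratio 0.
    """
    basis = lmap.basis
    if basis.shape[0] == 0:
        return x.copy(), 0.0
    K = int(rng.integers(1, config.maxnumbasis + 1))
    y = x.copy()
    steps: list[tuple[int, int]] = []
    log_q_fwd = 0.0
    for _ in range(K):
        adm = _admissible(y, basis)
        if adm.shape[0] == 0:
            # a mid-path dead end breaks the forward/reverse path pairing;
            # abandon the whole proposal (chain stays put)
            return x.copy(), 0.0
        pick = adm[rng.integers(adm.shape[0])]
        log_q_fwd -= np.log(adm.shape[0])
        i, s = int(pick[0]), int(pick[1])
        y = y + s * basis[i]
        steps.append((i, s))
    if not steps:
        return x.copy(), 0.0
    # reverse path: apply negated steps in reverse order from y back to x
    log_q_rev = 0.0
    z = y.copy()
    for i, s in reversed(steps):
        adm = _admissible(z, basis)
        # the reverse step (i, -s) must itself be admissible at z
        log_q_rev -= np.log(adm.shape[0])
        z = z - s * basis[i]
    assert np.array_equal(z, x)
    return y, log_q_rev - log_q_fwd


def accept_move(
    x: np.ndarray,
    x_proposed: np.ndarray,
    log_proposal_ratio: float,
    log_cell_prob_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Metropolis-Hastings accept/reject between feasible configurations.

    ``log_cell_prob_fn`` evaluates the complete-data log-probability of a
    frequency vector under the current model parameters.
    """
    if np.array_equal(x, x_proposed):
        return x, True
    log_ratio = (
        log_cell_prob_fn(x_proposed) - log_cell_prob_fn(x) + log_proposal_ratio
    )
    if np.log(rng.uniform()) < log_ratio:
        return x_proposed, True
    return x, False


def update_frequencies(
    x: np.ndarray,
    lmap: LatentMap,
    config: SamplerConfig,
    log_cell_prob_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One propose/accept cycle on the latent frequency vector."""
    x_prop, log_ratio = propose_move(x, lmap, config, rng)
    return accept_move(x, x_prop, log_ratio, log_cell_prob_fn, rng)
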