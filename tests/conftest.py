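"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import gammaln

from latentmark.histories import LatentMap


def brute_force_feasible(lmap: LatentMap, max_count: int | None = None) -> list[np.ndarray]:
    """Enumerate {x >= 0 : A^T x = observed_counts} by depth-first search.

    Independent of the sampler: assigns frequencies history by history,
    bounding each by the remaining class counts and pruning infeasible
    branches; every returned vector is re-verified against A^T x = counts.
    """
    A = lmap.A
    counts = lmap.observed_counts
    order = list(np.argsort(-A.sum(axis=1)))  # multi-class rows first
    out: list[np.ndarray] = []
    x = np.zeros(lmap.n_histories, dtype=np.int64)

    # classes of history j not touched by any later history must be
    # exhausted by x_j itself: such assignments are forced, not branched
    later_touches = []
    for i, j in enumerate(order):
        later = np.zeros(A.shape[1], dtype=bool)
        for jj in order[i + 1:]:
            later |= A[jj] > 0
        later_touches.append(later)

    def rec(i: int, rem: np.ndarray) -> None:
        if i == len(order):
            if not rem.any():
                out.append(x.copy())
            return
        j = order[i]
        row = np.flatnonzero(A[j])
        ub = int(rem[row].min()) if row.size else 0
        exclusive = [c for c in row if not later_touches[i][c]]
        lb = max((int(rem[c]) for c in exclusive), default=0)
        if lb > ub:
            x[j] = 0
            return
        for v in range(ub, lb - 1, -1):
            x[j] = v
            rec(i + 1, rem - v * A[j])
        x[j] = 0

    rec(0, counts.copy())
    for xv in out:
        assert np.array_equal(A.T @ xv, counts)
    return out


def exact_state_probs(
    feasible: list[np.ndarray],
    log_cells: np.ndarray,
    extra_log_target=None,
) -> np.ndarray:
    """Exact conditional probabilities over an enumerated feasible set.

    The weight of a configuration is the latent-multinomial one:
    n!/prod_j x_j! * prod_j cell_j^x_j (times any extra term in n).
    """
    lw = []
    for x in feasible:
        n = int(x.sum())
        w = float(log_cells @ x + gammaln(n + 1) - gammaln(x + 1).sum())
        if extra_log_target is not None:
            w += extra_log_target(n)
        lw.append(w)
    lw = np.array(lw)
    p = np.exp(lw - lw.max())
    return p / p.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_record_toy():
    """One type-1 and one type-2 record: the smallest mergeable system."""
    from latentmark import process_data

    return process_data([[1, 0], [0, 2]], "never")
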