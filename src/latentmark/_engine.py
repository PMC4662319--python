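"""Shared machinery for the CJS and closed-population samplers.

Both models carry the same latent structure: a feasible frequency vector
``x`` over admissible latent histories, realized as a pool of individual
"slots" (each active slot holds one latent individual's history index and
any individual-level random effects).  The latent-frequency Metropolis step,
the slot bookkeeping for merge/split moves, and the conjugate updates for
the encounter-type probabilities (delta, alpha) live here.

The Metropolis chain operates on the pool of distinguishable latent
individuals (each slot carries its own random effects), whose stationary
law marginalizes to the latent-multinomial posterior over frequency
vectors, multiplicity ``n!/prod_j x_j!`` included.  Individual effects for
newly created individuals are proposed from their prior, so their prior
densities cancel and the acceptance ratio involves only the (q-marginal)
cell probabilities of the individuals that the move removes or creates,
plus counting and choice factors (see ``latent_step``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import gammaln

from .histories import LatentMap
from .latent import SamplerConfig, propose_move

__all__ = [
    "Priors",
    "sample_sigma2_invgamma",
    "SlotPool",
    "encounter_type_counts",
    "update_delta",
    "update_alpha",
    "latent_step",
    "sample_sigma2_halfcauchy",
]


@dataclass
class Priors:
    """Default "uninformative" priors.

    beta ~ Normal(0, variance ``beta_var``); delta ~ Dirichlet(1,1,1) when
    type-specific or uniform on the simplex slice when shared; alpha ~
    Beta(1,1); the closed model's individual-effect SD has a half-Cauchy
    (``sigma_scale``) prior and its N the scale prior 1/N.  The CJS
    individual-effect variances use a weakly informative conjugate
    Inverse-Gamma(``sigma2_shape``, ``sigma2_rate``) prior: survival
    heterogeneity is only weakly identified in CJS data (extreme variances
    mimic an immortal/instant-death mixture), so a heavy-tailed scale prior
    lets the posterior escape to degenerate regimes.
    """

    beta_var: float = 1.75
    sigma_scale: float = 25.0
    sigma2_shape: float = 2.0
    sigma2_rate: float = 0.1
    delta_dirichlet: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alpha_beta: tuple[float, float] = (1.0, 1.0)


@dataclass
class SlotPool:
    """Pool of latent-individual slots.

    ``hist`` maps slot -> history index (-1 = inactive).  ``z`` holds named
    per-slot random effects (zeros when the model has no heterogeneity).
    """

    hist: np.ndarray
    z: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_frequencies(cls, x: np.ndarray, z_names: tuple[str, ...]) -> "SlotPool":
        n_cap = int(x.sum())
        hist = np.full(n_cap, -1, dtype=np.int64)
        pos = 0
        for j, cnt in enumerate(np.asarray(x, dtype=np.int64)):
            hist[pos : pos + cnt] = j
            pos += cnt
        return cls(hist=hist, z={name: np.zeros(n_cap) for name in z_names})

    @property
    def active(self) -> np.ndarray:
        return np.flatnonzero(self.hist >= 0)

    @property
    def n(self) -> int:
        return int((self.hist >= 0).sum())

    def frequencies(self, n_histories: int) -> np.ndarray:
        return np.bincount(self.hist[self.hist >= 0], minlength=n_histories).astype(
            np.int64
        )


def encounter_type_counts(x: np.ndarray, codes_matrix: np.ndarray) -> np.ndarray:
    """Counts of encounter types 1..4 implied by a latent frequency vector."""
    out = np.zeros(4, dtype=np.int64)
    for c in range(1, 5):
        out[c - 1] = int(((codes_matrix == c).sum(axis=1) * x).sum())
    return out


def update_delta(
    counts: np.ndarray,
    mode: str,
    priors: Priors,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Conjugate update of (delta_1, delta_2) given encounter-type counts.

    ``mode`` "type" draws (delta_1, delta_2, 1-d1-d2) from its Dirichlet full
    conditional; "shared" (delta_1 = delta_2 = d) exploits that u = 2d is
    Beta-distributed given the counts.
    """
    c1, c2, c3, c4 = (int(v) for v in counts)
    cb = c3 + c4
    if mode == "type":
        a = priors.delta_dirichlet
        draw = rng.dirichlet([a[0] + c1, a[1] + c2, a[2] + cb])
        return float(draw[0]), float(draw[1])
    if mode == "shared":
        u = rng.beta(1.0 + c1 + c2, 1.0 + cb)
        return float(u / 2.0), float(u / 2.0)
    raise ValueError(f"unknown delta mode {mode!r}")


def update_alpha(
    counts: np.ndarray,
    data_type: str,
    priors: Priors,
    rng: np.random.Generator,
) -> float:
    """Beta full-conditional update of alpha; fixed 0/1 for never/always."""
    if data_type == "never":
        return 0.0
    if data_type == "always":
        return 1.0
    a, b = priors.alpha_beta
    return float(rng.beta(a + int(counts[3]), b + int(counts[2])))


def sample_sigma2_invgamma(
    z: np.ndarray,
    shape: float,
    rate: float,
    rng: np.random.Generator,
) -> float:
    """Conjugate inverse-gamma update of an individual-effect variance."""
    post_shape = shape + 0.5 * z.size
    post_rate = rate + 0.5 * float(z @ z)
    return float(1.0 / rng.gamma(post_shape, 1.0 / post_rate))


def sample_sigma2_halfcauchy(
    z: np.ndarray,
    aux: float,
    scale: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Gibbs update of (sigma^2, auxiliary) under sigma ~ half-Cauchy(scale).

    Uses the inverse-gamma mixture representation: sigma^2 | a ~ IG(1/2, 1/a),
    a ~ IG(1/2, 1/scale^2) gives sigma ~ half-Cauchy(scale); both full
    conditionals are inverse-gamma, keeping the sweep a pure Gibbs sampler.
    """
    n = z.size
    shape = 0.5 * (n + 1)
    rate = 1.0 / aux + 0.5 * float(z @ z)
    sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)
    aux_new = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / scale**2 + 1.0 / sigma2))
    return float(sigma2), float(aux_new)


def latent_step(
    x: np.ndarray,
    lmap: LatentMap,
    pool: SlotPool,
    config: SamplerConfig,
    rng: np.random.Generator,
    log_cell_fn: Callable[[np.ndarray, dict[str, np.ndarray]], np.ndarray],
    draw_z_fn: Callable[[int, np.random.Generator], dict[str, np.ndarray]],
    extra_log_target_fn: Optional[Callable[[int], float]] = None,
) -> tuple[np.ndarray, bool]:
    """One Metropolis update of the latent frequencies, with slot bookkeeping.

    ``log_cell_fn(hist_idx, z)`` returns the q-marginal complete-data log
    cell probability for individuals with the given history indices and
    effects; ``draw_z_fn`` proposes effects for newly created individuals
    from their prior; ``extra_log_target_fn(n)`` supplies any extra target
    terms that depend on the number of detected individuals (the closed
    model's ``(1-p*)^(N-n) C(N, n)``).  Mutates ``pool`` on acceptance and
    returns the (possibly new) frequency vector and an acceptance flag.
    """
    x_prop, basis_log_ratio = propose_move(x, lmap, config, rng)
    delta = x_prop - x
    if not delta.any():
        return x, False

    removed_hists = np.flatnonzero(delta < 0)
    added_hists = np.flatnonzero(delta > 0)

    # choose which individuals realize the removals (uniform among matches)
    removed_slots: list[int] = []
    for j in removed_hists:
        cand = np.flatnonzero(pool.hist == j)
        pick = rng.choice(cand.size, size=-int(delta[j]), replace=False)
        removed_slots.extend(cand[pick].tolist())
    removed_slots_arr = np.asarray(removed_slots, dtype=np.int64)

    added_list = np.repeat(added_hists, delta[added_hists])
    z_new = draw_z_fn(added_list.size, rng)

    n_old, n_new = int(x.sum()), int(x_prop.sum())
    # Counting part of the acceptance ratio.  Individuals are exchangeable
    # but distinguishable (slots carry their own random effects): the target
    # over configurations carries n!/prod_j x_j!, the proposal removes a
    # uniformly chosen subset of the x_j duplicates (binomial choice
    # factors) and creates added individuals as an unordered batch (d_j!
    # and a_j! multiset factors).  Everything collapses to falling
    # factorials: log n'! - log n! + sum_j log[x_j!/(x_j-d_j)!]
    # - sum_j log[x'_j!/(x'_j-a_j)!].  Verified against brute-force
    # enumeration with duplicate records and multi-step (K=2) moves.
    log_mult = gammaln(n_new + 1) - gammaln(n_old + 1)
    d_j = -delta[removed_hists]
    a_j = delta[added_hists]
    log_choice = float(
        (gammaln(x[removed_hists] + 1) - gammaln(x[removed_hists] - d_j + 1)).sum()
        - (gammaln(x_prop[added_hists] + 1) - gammaln(x_prop[added_hists] - a_j + 1)).sum()
    )

    log_cells_added = (
        float(log_cell_fn(added_list, z_new).sum()) if added_list.size else 0.0
    )
    if removed_slots_arr.size:
        z_old = {k: v[removed_slots_arr] for k, v in pool.z.items()}
        log_cells_removed = float(
            log_cell_fn(pool.hist[removed_slots_arr], z_old).sum()
        )
    else:
        log_cells_removed = 0.0

    log_alpha = (
        basis_log_ratio + log_mult + log_choice + log_cells_added - log_cells_removed
    )
    if extra_log_target_fn is not None:
        log_alpha += extra_log_target_fn(n_new) - extra_log_target_fn(n_old)

    if np.log(rng.uniform()) >= log_alpha:
        return x, False

    # apply: deactivate removed slots, activate free slots for additions
    pool.hist[removed_slots_arr] = -1
    free = np.flatnonzero(pool.hist < 0)
    take = free[: added_list.size]
    pool.hist[take] = added_list
    for name, arr in pool.z.items():
        arr[take] = z_new[name]
    return x_prop, True
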