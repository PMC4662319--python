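"""Two-mark Cormack-Jolly-Seber model.

Conditional on each latent individual's first capture ``C_i``, occasions
``t = C_i+1..T`` contribute per-occasion factors

=========  =====================================================
code       factor
=========  =====================================================
0          ``(1-p_it) phi_i,t-1`` if alive (``q_it = 1``),
           ``(1-phi_i,t-1)`` at death, 1 once dead
1          ``p_it delta_1 phi_i,t-1``
2          ``p_it delta_2 phi_i,t-1``
3          ``p_it (1-d1-d2)(1-alpha) phi_i,t-1``
4          ``p_it (1-d1-d2) alpha phi_i,t-1``
=========  =====================================================

Detection and survival use the probit link, which admits a full Gibbs sweep
via truncated-normal data augmentation: latent utilities for every realized
detection/survival Bernoulli outcome, multivariate-normal draws for the
coefficients, normal draws for individual effects, and conjugate inverse-gamma draws for their variances.  Alive states are
sampled explicitly (an exact categorical draw of each individual's death
time after its last detection), the encounter-type probabilities
``(delta_1, delta_2)`` and ``alpha`` have Dirichlet/Beta full conditionals,
and the latent frequency vector is updated once per sweep by the feasible
basis-move Metropolis step.  The encounter type observed at first capture
is a free draw from the delta/alpha distribution and is included in the
sampler's complete-data target, so histories first encountered on the last
occasion still inform delta and alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import ndtr, ndtri

from ._engine import (
    Priors,
    SlotPool,
    encounter_type_counts,
    latent_step,
    sample_sigma2_invgamma,
    update_alpha,
    update_delta,
)
from .design import build_design, parse_formula
from .histories import LatentMap, ObservedData, initialize_frequencies, process_data
from .latent import SamplerConfig
from .posterior import PosteriorSamples

__all__ = ["cjs_cell_logprob", "cjs_history_logprob", "fit_cjs", "mark_cjs"]

_EPS = 1e-300


def _type_factors(delta1: float, delta2: float, alpha: float) -> np.ndarray:
    """Conditional encounter-type probabilities indexed by code 0..4."""
    both = max(1.0 - delta1 - delta2, 0.0)
    return np.array(
        [1.0, delta1, delta2, both * (1.0 - alpha), both * alpha]
    )


def cjs_cell_logprob(
    codes: Sequence[int],
    p: np.ndarray,
    phi: np.ndarray,
    delta1: float,
    delta2: float,
    alpha: float,
    q: Optional[Sequence[int]] = None,
) -> float:
    """Log cell probability of one latent history (product over t > C_i).

    ``p`` has length ``T`` (per-occasion detection), ``phi`` length ``T-1``
    (per-interval survival).  With ``q`` given, nondetections use the branch
    ``(1-p)phi q + (1-phi)(1-q)`` at the given alive states and occasions
    after a known death contribute a factor 1; with ``q=None`` the alive
    states after the last detection are marginalized by backward recursion.
    The encounter type at the first capture occasion is *not* included here
    (see :func:`cjs_history_logprob`).
    """
    codes = np.asarray(codes, dtype=np.int64)
    T = codes.size
    if not np.all((codes >= 0) & (codes <= 4)):
        raise ValueError("codes must be in 0..4")
    det = np.flatnonzero(codes > 0)
    if det.size == 0:
        return 0.0
    C0, L0 = int(det[0]), int(det[-1])
    tf = _type_factors(delta1, delta2, alpha)
    p = np.asarray(p, dtype=float)
    phi = np.asarray(phi, dtype=float)
    log_prob = 0.0
    for t0 in range(C0 + 1, L0 + 1):
        c = codes[t0]
        if c > 0:
            log_prob += np.log(p[t0] * tf[c] * phi[t0 - 1] + _EPS)
        else:
            log_prob += np.log((1.0 - p[t0]) * phi[t0 - 1] + _EPS)
    if q is None:
        chi = 1.0
        for t0 in range(T - 1, L0, -1):
            chi = (1.0 - phi[t0 - 1]) + phi[t0 - 1] * (1.0 - p[t0]) * chi
        log_prob += np.log(chi + _EPS)
    else:
        q = np.asarray(q, dtype=np.int64)
        for t0 in range(L0 + 1, T):
            if q[t0 - 1] == 0:
                continue  # known dead before t: factor 1
            if q[t0] == 1:
                log_prob += np.log((1.0 - p[t0]) * phi[t0 - 1] + _EPS)
            else:
                log_prob += np.log(1.0 - phi[t0 - 1] + _EPS)
    return float(log_prob)


def cjs_history_logprob(
    codes: Sequence[int],
    p: np.ndarray,
    phi: np.ndarray,
    delta1: float,
    delta2: float,
    alpha: float,
) -> float:
    """Complete-data log probability of a latent history for the sampler.

    Adds the encounter-type factor for the first-capture occasion to the
    q-marginal :func:`cjs_cell_logprob`; this is the per-individual term the
    latent-frequency update and the delta/alpha full conditionals share.
    """
    codes_arr = np.asarray(codes, dtype=np.int64)
    det = np.flatnonzero(codes_arr > 0)
    if det.size == 0:
        return 0.0
    tf = _type_factors(delta1, delta2, alpha)
    first_factor = float(np.log(tf[codes_arr[det[0]]] + _EPS))
    return first_factor + cjs_cell_logprob(codes, p, phi, delta1, delta2, alpha)


def _trunc_norm_utilities(
    eta: np.ndarray, outcome: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Albert-Chib latent utilities: N(eta,1) truncated by outcome sign."""
    u = rng.uniform(size=eta.shape)
    lo = ndtr(-eta)  # P(eta + e < 0)
    cdf = np.where(outcome, lo + u * (1.0 - lo), u * lo)
    cdf = np.clip(cdf, 1e-12, 1.0 - 1e-12)
    return eta + ndtri(cdf)


def _draw_beta(
    X_rows: np.ndarray,
    resid: np.ndarray,
    prior_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """MVN full-conditional draw for probit coefficients.

    ``X_rows`` is (m, k) over the realized Bernoulli outcomes, ``resid`` the
    utilities minus the individual-effect part.
    """
    k = X_rows.shape[1]
    prec = X_rows.T @ X_rows + np.eye(k) / prior_var
    rhs = X_rows.T @ resid
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    return mean + np.linalg.solve(chol.T, rng.standard_normal(k))



@dataclass
class _CJSSetup:
    lmap: LatentMap
    codes: np.ndarray  # (H, T)
    first0: np.ndarray  # (H,) 0-based first-capture occasion
    last0: np.ndarray  # (H,) 0-based last-detection occasion
    T: int


def _history_tables(lmap: LatentMap) -> _CJSSetup:
    codes = lmap.codes_matrix
    det = codes > 0
    first0 = det.argmax(axis=1)
    last0 = codes.shape[1] - 1 - det[:, ::-1].argmax(axis=1)
    return _CJSSetup(lmap, codes, first0, last0, codes.shape[1])


def _resolve_setup(data, data_type, covariates):
    if isinstance(data, tuple):
        obs, lmap = data
    elif isinstance(data, ObservedData):
        from .histories import build_latent_map

        obs, lmap = data, build_latent_map(data)
    else:
        if data_type is None:
            raise ValueError("data_type is required with a raw encounter matrix")
        obs, lmap = process_data(data, data_type, covariates=covariates)
    return obs, lmap


def fit_cjs(
    data,
    mod_p: str = "~1",
    mod_phi: str = "~1",
    mod_delta: str = "~type",
    data_type: Optional[str] = None,
    covariates=None,
    priors: Optional[Priors] = None,
    chains: int = 1,
    iter: int = 12000,
    burnin: int = 2000,
    thin: int = 1,
    seed: Optional[Union[int, np.random.SeedSequence]] = None,
    parms: Union[str, Sequence[str]] = ("pbeta", "phibeta", "delta", "alpha"),
    maxnumbasis: int = 1,
) -> PosteriorSamples:
    """Fit the two-mark CJS model by MCMC.

    ``data`` is a ``(ObservedData, LatentMap)`` pair from
    :func:`~latentmark.histories.process_data`, an :class:`ObservedData`, or
    a raw encounter matrix together with ``data_type``.  ``mod_delta`` is
    ``"~type"`` (delta_1 != delta_2) or ``"~1"`` (shared).  ``parms`` selects
    monitored parameters ("all" monitors everything, including the latent
    configuration, as required for multimodel inference).  Draws are
    reproducible given ``seed``; with ``chains > 1``, chains are
    independently seeded streams.
    """
    if iter <= burnin:
        raise ValueError("iter must exceed burnin")
    priors = priors or Priors()
    obs, lmap = _resolve_setup(data, data_type, covariates)
    covariates = covariates if covariates is not None else obs.covariates
    tables = _history_tables(lmap)
    T = tables.T
    mf_p, mf_phi = parse_formula(mod_p), parse_formula(mod_phi)
    if mod_delta not in ("~type", "~1", "fixed"):
        raise ValueError('mod_delta must be "~type", "~1" or "fixed"')
    delta_mode = {"~type": "type", "~1": "shared", "fixed": "fixed"}[mod_delta]
    monitor = _resolve_parms(parms, mf_p, mf_phi, obs.data_type, delta_mode)

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    chain_seeds = ss.spawn(chains)
    nsave = (iter - burnin) // thin
    all_chains = []
    extras: dict[str, list] = {"slot_hist": [], "zp": [], "zphi": []}
    accept_rates = []
    names: list[str] = []
    for c in range(chains):
        draws, names, ext, acc = _run_chain_cjs(
            tables, obs, mf_p, mf_phi, delta_mode, priors, iter, burnin, thin,
            np.random.default_rng(chain_seeds[c]), monitor, maxnumbasis,
            covariates, nsave,
        )
        all_chains.append(draws)
        for k in extras:
            extras[k].append(ext[k])
        accept_rates.append(acc)
    samples = PosteriorSamples(
        np.stack(all_chains),
        names,
        metadata={
            "model": "cjs",
            "mod_p": mf_p.formula,
            "mod_phi": mf_phi.formula,
            "mod_delta": mod_delta,
            "data_type": obs.data_type,
            "iter": iter,
            "burnin": burnin,
            "thin": thin,
            "chains": chains,
            "T": T,
            "n1": obs.n1,
            "n2": obs.n2,
            "n_known": obs.n_known,
            "latent_accept_rate": float(np.mean(accept_rates)),
            "maxnumbasis": maxnumbasis,
        },
    )
    if monitor["all"]:
        samples.extras = {k: np.stack(v) for k, v in extras.items()}
        samples.metadata["n_histories"] = lmap.n_histories
    return samples


def _resolve_parms(parms, mf_p, mf_phi, data_type, delta_mode) -> dict:
    want_all = parms == "all"
    req = set() if want_all else set([parms] if isinstance(parms, str) else parms)
    known = {"pbeta", "phibeta", "delta", "alpha", "sigma2_zp", "sigma2_zphi"}
    bad = req - known
    if bad:
        raise ValueError(f"unknown parms {sorted(bad)}")
    if "sigma2_zp" in req and not mf_p.has_h:
        raise ValueError("sigma2_zp monitored but mod.p has no ~h term")
    if "sigma2_zphi" in req and not mf_phi.has_h:
        raise ValueError("sigma2_zphi monitored but mod.phi has no ~h term")
    if "alpha" in req and data_type != "sometimes":
        req.discard("alpha")
    if delta_mode == "fixed":
        req.discard("delta")
        req.discard("alpha")
    return {
        "all": want_all,
        "pbeta": want_all or "pbeta" in req,
        "phibeta": want_all or "phibeta" in req,
        "delta": (want_all or "delta" in req) and delta_mode != "fixed",
        "alpha": (want_all or "alpha" in req) and data_type == "sometimes"
                 and delta_mode != "fixed",
        "sigma2_zp": (want_all or "sigma2_zp" in req) and mf_p.has_h,
        "sigma2_zphi": (want_all or "sigma2_zphi" in req) and mf_phi.has_h,
    }


def _run_chain_cjs(
    tables: _CJSSetup,
    obs: ObservedData,
    mf_p,
    mf_phi,
    delta_mode: str,
    priors: Priors,
    iters: int,
    burnin: int,
    thin: int,
    rng: np.random.Generator,
    monitor: dict,
    maxnumbasis: int,
    covariates,
    nsave: int,
):
    lmap, codes, first0, last0, T = (
        tables.lmap,
        tables.codes,
        tables.first0,
        tables.last0,
        tables.T,
    )
    x = initialize_frequencies(lmap)
    pool = SlotPool.from_frequencies(x, ("zp", "zphi"))
    n_cap = pool.hist.size
    cfg = SamplerConfig(maxnumbasis=maxnumbasis)

    _Xp_shared = None if mf_p.depends_on_first_capture else build_design(
        mf_p, T, "p", covariates=covariates
    ).X
    _Xphi_shared = None if mf_phi.depends_on_first_capture else build_design(
        mf_phi, T, "phi", covariates=covariates
    ).X

    def designs_for(fc0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Design tensors for individuals with the given first captures."""
        Xp = _Xp_shared if _Xp_shared is not None else build_design(
            mf_p, T, "p", first_capture=fc0 + 1, covariates=covariates
        ).X
        Xphi = _Xphi_shared if _Xphi_shared is not None else build_design(
            mf_phi, T, "phi", first_capture=fc0 + 1, covariates=covariates
        ).X
        return Xp, Xphi

    names_p = build_design(mf_p, T, "p",
                           first_capture=np.ones(1, dtype=np.int64) if mf_p.depends_on_first_capture else None,
                           covariates=covariates).names
    names_phi = build_design(mf_phi, T, "phi",
                             first_capture=np.ones(1, dtype=np.int64) if mf_phi.depends_on_first_capture else None,
                             covariates=covariates).names
    kp, kphi = len(names_p), len(names_phi)

    beta_p = np.zeros(kp)
    beta_phi = np.zeros(kphi)
    sigma2_zp = 0.25
    sigma2_zphi = 0.25
    if delta_mode == "fixed":
        delta1, delta2 = 1.0, 0.0
        alpha = 0.0
    else:
        delta1 = delta2 = 0.35
        alpha = {"never": 0.0, "always": 1.0}.get(obs.data_type, 0.5)
    q = np.ones((n_cap, T), dtype=np.int64)

    def slot_designs():
        fc0 = np.where(pool.hist >= 0, first0[np.clip(pool.hist, 0, None)], 0)
        return designs_for(fc0)

    def eta_parts(a_idx, Xp, Xphi):
        Xp_a = Xp if Xp.shape[0] == 1 else Xp[a_idx]
        Xphi_a = Xphi if Xphi.shape[0] == 1 else Xphi[a_idx]
        eta_p = Xp_a @ beta_p
        eta_phi = Xphi_a @ beta_phi
        if Xp.shape[0] == 1:
            eta_p = np.broadcast_to(eta_p, (a_idx.size, T)).copy()
            eta_phi = np.broadcast_to(eta_phi, (a_idx.size, T - 1)).copy()
        if mf_p.has_h:
            eta_p = eta_p + pool.z["zp"][a_idx, None]
        if mf_phi.has_h:
            eta_phi = eta_phi + pool.z["zphi"][a_idx, None]
        return Xp_a, Xphi_a, eta_p, eta_phi

    def log_cells(hist_idx: np.ndarray, z: dict[str, np.ndarray]) -> np.ndarray:
        """q-marginal complete-data log cell per candidate individual,
        including the first-capture encounter-type factor."""
        m = hist_idx.size
        Xp, Xphi = designs_for(first0[hist_idx])
        eta_p = (Xp if Xp.shape[0] != 1 else np.broadcast_to(Xp, (m, T, Xp.shape[2]))) @ beta_p
        eta_phi = (Xphi if Xphi.shape[0] != 1 else np.broadcast_to(Xphi, (m, T - 1, Xphi.shape[2]))) @ beta_phi
        if mf_p.has_h:
            eta_p = eta_p + z["zp"][:, None]
        if mf_phi.has_h:
            eta_phi = eta_phi + z["zphi"][:, None]
        p = ndtr(eta_p)
        phi = ndtr(eta_phi)
        tf = _type_factors(delta1, delta2, alpha)
        cds = codes[hist_idx]
        C0, L0 = first0[hist_idx], last0[hist_idx]
        occ = np.arange(T)
        inside = (occ[None, :] > C0[:, None]) & (occ[None, :] <= L0[:, None])
        detected = cds > 0
        lp = np.zeros(m)
        # first-capture encounter type
        lp += np.log(tf[cds[np.arange(m), C0]] + _EPS)
        # occasions strictly after first capture, up to last detection
        contrib = np.where(
            detected,
            np.log(p * tf[cds] * np.concatenate([np.ones((m, 1)), phi], axis=1) + _EPS),
            np.log((1.0 - p) * np.concatenate([np.ones((m, 1)), phi], axis=1) + _EPS),
        )
        lp += np.where(inside, contrib, 0.0).sum(axis=1)
        # marginal tail after last detection
        chi = np.ones(m)
        for t0 in range(T - 1, 0, -1):
            chi_new = (1.0 - phi[:, t0 - 1]) + phi[:, t0 - 1] * (1.0 - p[:, t0]) * chi
            chi = np.where(L0 < t0, chi_new, chi)
        lp += np.log(chi + _EPS)
        return lp

    def draw_z(m: int, rng_: np.random.Generator) -> dict[str, np.ndarray]:
        return {
            "zp": rng_.normal(0, np.sqrt(sigma2_zp), m) if mf_p.has_h else np.zeros(m),
            "zphi": rng_.normal(0, np.sqrt(sigma2_zphi), m) if mf_phi.has_h else np.zeros(m),
        }

    draws = np.zeros((nsave, 0))
    cols: list[str] = []
    n_latent_updates = 0
    n_latent_accept = 0
    saved = 0
    rec_slot_hist = np.full((nsave, n_cap), -1, dtype=np.int16) if monitor["all"] else None
    rec_zp = np.zeros((nsave, n_cap)) if monitor["all"] else None
    rec_zphi = np.zeros((nsave, n_cap)) if monitor["all"] else None
    rec_rows: list[np.ndarray] = []

    for it in range(iters):
        # --- latent frequency update ---
        x, accepted = latent_step(x, lmap, pool, cfg, rng, log_cells, draw_z)
        n_latent_updates += 1
        n_latent_accept += int(accepted)

        a_idx = pool.active
        hist_a = pool.hist[a_idx]
        Xp, Xphi = slot_designs()
        Xp_a, Xphi_a, eta_p, eta_phi = eta_parts(a_idx, Xp, Xphi)
        p_a = ndtr(eta_p)
        phi_a = ndtr(eta_phi)
        cds_a = codes[hist_a]
        fc0_a = first0[hist_a]
        ld0_a = last0[hist_a]
        n_act = a_idx.size
        occ0 = np.arange(T)

        # --- alive states: exact death-time draw after last detection ---
        b = np.ones((n_act, T))
        j_after = occ0[None, :] > ld0_a[:, None]
        b[:, 1:] = np.where(
            j_after[:, 1:], phi_a * (1.0 - p_a[:, 1:]), 1.0
        )
        cq = np.cumprod(b, axis=1)
        w = np.zeros((n_act, T))
        w[:, : T - 1] = cq[:, : T - 1] * (1.0 - phi_a)
        w[:, T - 1] = cq[:, T - 1]
        w[occ0[None, :] < ld0_a[:, None]] = 0.0
        w /= w.sum(axis=1, keepdims=True)
        u = rng.uniform(size=(n_act, 1))
        d0 = (np.cumsum(w, axis=1) < u).sum(axis=1)
        q_a = (occ0[None, :] <= d0[:, None]).astype(np.int64)
        q[a_idx] = q_a

        # --- probit augmentation: detection ---
        Mp = (occ0[None, :] > fc0_a[:, None]) & (q_a == 1)
        if Mp.any():
            out_p = cds_a > 0
            u_p = _trunc_norm_utilities(eta_p[Mp], out_p[Mp], rng)
            Xp_full = Xp_a if Xp_a.shape[0] == n_act else np.broadcast_to(Xp_a, (n_act, T, kp))
            Xrows = Xp_full[Mp]
            zpart = pool.z["zp"][a_idx, None] if mf_p.has_h else np.zeros((n_act, 1))
            zrep = np.broadcast_to(zpart, (n_act, T))[Mp]
            beta_p = _draw_beta(Xrows, u_p - zrep, priors.beta_var, rng)
            if mf_p.has_h:
                eta_fixed = Xp_full @ beta_p
                u_mat = np.zeros((n_act, T))
                u_mat[Mp] = u_p
                resid = np.where(Mp, u_mat - eta_fixed, 0.0)
                m_i = Mp.sum(axis=1)
                prec = m_i + 1.0 / sigma2_zp
                mean = resid.sum(axis=1) / prec
                znew = mean + rng.standard_normal(n_act) / np.sqrt(prec)
                sigma2_zp = sample_sigma2_invgamma(
                    znew, priors.sigma2_shape, priors.sigma2_rate, rng
                )
                pool.z["zp"][a_idx] = znew

        # --- probit augmentation: survival ---
        int0 = np.arange(T - 1)  # interval from occasion int0+1 to int0+2
        Mphi = (int0[None, :] >= fc0_a[:, None]) & (q_a[:, :-1] == 1)
        if Mphi.any():
            out_phi = q_a[:, 1:] == 1
            u_phi = _trunc_norm_utilities(eta_phi[Mphi], out_phi[Mphi], rng)
            Xphi_full = Xphi_a if Xphi_a.shape[0] == n_act else np.broadcast_to(Xphi_a, (n_act, T - 1, kphi))
            Xrows = Xphi_full[Mphi]
            zpart = pool.z["zphi"][a_idx, None] if mf_phi.has_h else np.zeros((n_act, 1))
            zrep = np.broadcast_to(zpart, (n_act, T - 1))[Mphi]
            beta_phi = _draw_beta(Xrows, u_phi - zrep, priors.beta_var, rng)
            if mf_phi.has_h:
                eta_fixed = Xphi_full @ beta_phi
                u_mat = np.zeros((n_act, T - 1))
                u_mat[Mphi] = u_phi
                resid = np.where(Mphi, u_mat - eta_fixed, 0.0)
                m_i = Mphi.sum(axis=1)
                prec = m_i + 1.0 / sigma2_zphi
                mean = resid.sum(axis=1) / prec
                znew = mean + rng.standard_normal(n_act) / np.sqrt(prec)
                sigma2_zphi = sample_sigma2_invgamma(
                    znew, priors.sigma2_shape, priors.sigma2_rate, rng
                )
                pool.z["zphi"][a_idx] = znew

        # --- encounter-type probabilities ---
        if delta_mode != "fixed":
            tcounts = encounter_type_counts(x, codes)
            delta1, delta2 = update_delta(tcounts, delta_mode, priors, rng)
            alpha = update_alpha(tcounts, obs.data_type, priors, rng)

        # --- record ---
        if it >= burnin and (it - burnin) % thin == 0:
            row, cols = _record_cjs(
                monitor, beta_p, beta_phi, delta1, delta2, alpha,
                sigma2_zp, sigma2_zphi, names_p, names_phi,
            )
            rec_rows.append(row)
            if monitor["all"]:
                rec_slot_hist[saved] = pool.hist.astype(np.int16)
                inact = pool.hist < 0
                zp_rec = pool.z["zp"].copy()
                zphi_rec = pool.z["zphi"].copy()
                if mf_p.has_h:
                    zp_rec[inact] = rng.normal(
                        0, np.sqrt(sigma2_zp), int(inact.sum())
                    )
                if mf_phi.has_h:
                    zphi_rec[inact] = rng.normal(
                        0, np.sqrt(sigma2_zphi), int(inact.sum())
                    )
                rec_zp[saved] = zp_rec
                rec_zphi[saved] = zphi_rec
            saved += 1

    draws = np.asarray(rec_rows)
    ext = {
        "slot_hist": rec_slot_hist if monitor["all"] else np.zeros((0, 0), dtype=np.int16),
        "zp": rec_zp if monitor["all"] else np.zeros((0, 0)),
        "zphi": rec_zphi if monitor["all"] else np.zeros((0, 0)),
    }
    return draws, cols, ext, n_latent_accept / max(n_latent_updates, 1)


def _record_cjs(
    monitor, beta_p, beta_phi, delta1, delta2, alpha,
    sigma2_zp, sigma2_zphi, names_p, names_phi,
):
    vals: list[float] = []
    cols: list[str] = []
    if monitor["pbeta"]:
        vals.extend(beta_p)
        cols.extend([f"pbeta[{n}]" for n in names_p])
    if monitor["phibeta"]:
        vals.extend(beta_phi)
        cols.extend([f"phibeta[{n}]" for n in names_phi])
    if monitor["alpha"]:
        vals.append(alpha)
        cols.append("alpha")
    if monitor["sigma2_zp"]:
        vals.append(sigma2_zp)
        cols.append("sigma2_zp")
    if monitor["sigma2_zphi"]:
        vals.append(sigma2_zphi)
        cols.append("sigma2_zphi")
    if monitor["delta"]:
        vals.extend([delta1, delta2])
        cols.extend(["delta_1", "delta_2"])
    return np.asarray(vals), cols


def mark_cjs(data, mod_p: str = "~1", mod_phi: str = "~1", **kwargs) -> PosteriorSamples:
    """Conventional single-mark CJS fit: histories over {0,1} only.

    A thin wrapper that fixes ``delta_1 = 1, delta_2 = 0`` so the two-mark
    machinery reduces exactly to a conventional probit CJS model.
    """
    kwargs.setdefault("data_type", "never")
    kwargs.setdefault("parms", ("pbeta", "phibeta"))
    return fit_cjs(data, mod_p=mod_p, mod_phi=mod_phi, mod_delta="fixed", **kwargs)
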