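"""Two-mark closed-population abundance model.

The semicomplete-data likelihood conditions the ``n`` detected latent
individuals' histories on detection (dividing by ``p*^n``, where ``p*`` is
the probability of being detected at least once) and multiplies by
``Binomial(n; N, p*)`` for the number detected out of ``N``.  Per-occasion
cell factors for a latent history are ``1-p`` (code 0), ``p delta_1`` (1),
``p delta_2`` (2), ``p (1-d1-d2)(1-alpha)`` (3) and ``p (1-d1-d2) alpha``
(4).  Detection uses the logit link; coefficients and individual effects
are updated by adaptive random-walk Metropolis (adaptation during burn-in
only), ``(delta_1, delta_2)`` and ``alpha`` have conjugate full
conditionals, ``N`` has an exact negative-binomial full conditional under
the scale prior ``1/N``, and the latent frequency vector is updated by the
feasible basis-move Metropolis step.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy import integrate
from scipy.special import expit, gammaln
from scipy.stats import norm

from ._engine import (
    Priors,
    SlotPool,
    encounter_type_counts,
    latent_step,
    update_alpha,
    update_delta,
)
from .design import build_design, parse_formula
from .histories import ObservedData, initialize_frequencies
from .latent import SamplerConfig
from .posterior import PosteriorSamples

__all__ = ["closed_cell_logprob", "compute_pstar", "update_N", "fit_closed", "mark_closed"]

_EPS = 1e-300


def _type_factors(delta1: float, delta2: float, alpha: float) -> np.ndarray:
    both = max(1.0 - delta1 - delta2, 0.0)
    return np.array([1.0, delta1, delta2, both * (1.0 - alpha), both * alpha])


def closed_cell_logprob(
    codes: Sequence[int],
    p: np.ndarray,
    delta1: float,
    delta2: float,
    alpha: float,
) -> float:
    """Log cell probability of one latent history (product over all occasions)."""
    codes = np.asarray(codes, dtype=np.int64)
    if not np.all((codes >= 0) & (codes <= 4)):
        raise ValueError("codes must be in 0..4")
    p = np.asarray(p, dtype=float)
    tf = _type_factors(delta1, delta2, alpha)
    factors = np.where(codes == 0, 1.0 - p, p * tf[codes])
    return float(np.log(factors + _EPS).sum())


def compute_pstar(
    eta: np.ndarray,
    sigma2_zp: float = 0.0,
    rtol: float = 1e-8,
) -> float:
    """Probability of being detected on at least one of ``T`` occasions.

    ``eta`` is the per-occasion linear predictor on the logit scale (the
    capture design at the individual-effect mean).  With ``sigma2_zp = 0``
    this is the closed form ``1 - prod_t (1 - logit^-1(eta_t))``; otherwise
    the individual effect is integrated out of the miss probability by
    adaptive quadrature to relative tolerance ``rtol``.
    """
    eta = np.asarray(eta, dtype=float)
    if sigma2_zp < 0:
        raise ValueError("sigma2_zp must be nonnegative")
    if sigma2_zp == 0.0:
        return float(1.0 - np.prod(1.0 - expit(eta)))
    sd = np.sqrt(sigma2_zp)

    def integrand(z: float) -> float:
        return float(np.prod(1.0 - expit(eta + z)) * norm.pdf(z, scale=sd))

    miss, err = integrate.quad(
        integrand, -10 * sd, 10 * sd, epsrel=rtol, epsabs=0.0, limit=200
    )
    if not np.isfinite(miss) or (miss > 0 and err / max(miss, 1e-12) > 1e-4):
        raise RuntimeError("p* integration did not converge")
    return float(1.0 - miss)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(50)


def _pstar_fast(eta: np.ndarray, sigma2_zp: float = 0.0) -> float:
    """Gauss-Hermite version of :func:`compute_pstar` for sampler hot loops
    (agrees with the adaptive quadrature to ~1e-10 for these integrands)."""
    if sigma2_zp == 0.0:
        return float(1.0 - np.prod(1.0 - expit(eta)))
    zs = np.sqrt(2.0 * sigma2_zp) * _GH_NODES
    miss = np.prod(1.0 - expit(eta[None, :] + zs[:, None]), axis=1)
    return float(1.0 - (miss @ _GH_WEIGHTS) / np.sqrt(np.pi))


def update_N(n: int, pstar: float, rng: np.random.Generator) -> int:
    """Exact draw of ``N`` from its full conditional under the prior 1/N.

    The conditional ``(1/N) C(N, n) (1-p*)^(N-n) p*^n`` is, in ``N - n``, a
    negative binomial with ``n`` successes and success probability ``p*``
    (since ``C(N,n)/N = C(N-1, n-1)/n``).
    """
    if n < 1:
        raise ValueError("the closed model conditions on n >= 1 detected individuals")
    if not 0.0 < pstar <= 1.0:
        raise ValueError("pstar must be in (0, 1]")
    if pstar == 1.0:
        return n
    return int(n + rng.negative_binomial(n, pstar))


class _AdaptiveScale:
    """Robbins-Monro scale adaptation toward a target acceptance rate,
    active during burn-in only."""

    def __init__(self, init: float = 0.2, target: float = 0.33):
        self.log_s = np.log(init)
        self.target = target
        self.t = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_s))

    def update(self, accepted: float, adapting: bool) -> None:
        self.t += 1
        if adapting:
            self.log_s += (accepted - self.target) / np.sqrt(1.0 + 0.1 * self.t)


def fit_closed(
    data,
    mod_p: str = "~1",
    mod_delta: str = "~type",
    data_type: Optional[str] = None,
    covariates=None,
    priors: Optional[Priors] = None,
    chains: int = 1,
    iter: int = 12000,
    burnin: int = 2000,
    thin: int = 1,
    seed: Optional[Union[int, np.random.SeedSequence]] = None,
    parms: Union[str, Sequence[str]] = ("pbeta", "N", "delta"),
    maxnumbasis: int = 1,
) -> PosteriorSamples:
    """Fit the two-mark closed-population abundance model by MCMC.

    Arguments mirror :func:`~latentmark.cjs.fit_cjs` (no survival model);
    default monitored parameters are the detection coefficients, ``N`` and
    ``(delta_1, delta_2)``.
    """
    if iter <= burnin:
        raise ValueError("iter must exceed burnin")
    priors = priors or Priors()
    from .cjs import _resolve_setup

    obs, lmap = _resolve_setup(data, data_type, covariates)
    covariates = covariates if covariates is not None else obs.covariates
    codes = lmap.codes_matrix
    T = codes.shape[1]
    mf_p = parse_formula(mod_p)
    if mod_delta not in ("~type", "~1", "fixed"):
        raise ValueError('mod_delta must be "~type", "~1" or "fixed"')
    delta_mode = {"~type": "type", "~1": "shared", "fixed": "fixed"}[mod_delta]
    monitor = _resolve_parms_closed(parms, mf_p, obs.data_type, delta_mode)

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    chain_seeds = ss.spawn(chains)
    nsave = (iter - burnin) // thin
    all_chains, extras, acc_meta = [], {"slot_hist": [], "zp": []}, []
    names: list[str] = []
    for c in range(chains):
        draws, names, ext, acc = _run_chain_closed(
            obs, lmap, codes, T, mf_p, delta_mode, priors, iter, burnin, thin,
            np.random.default_rng(chain_seeds[c]), monitor, maxnumbasis,
            covariates, nsave,
        )
        all_chains.append(draws)
        for k in extras:
            extras[k].append(ext[k])
        acc_meta.append(acc)
    samples = PosteriorSamples(
        np.stack(all_chains),
        names,
        metadata={
            "model": "closed",
            "mod_p": mf_p.formula,
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
            "acceptance": acc_meta,
            "maxnumbasis": maxnumbasis,
        },
    )
    if monitor["all"]:
        samples.extras = {k: np.stack(v) for k, v in extras.items()}
        samples.metadata["n_histories"] = lmap.n_histories
    return samples


def _resolve_parms_closed(parms, mf_p, data_type, delta_mode="type") -> dict:
    want_all = parms == "all"
    req = set() if want_all else set([parms] if isinstance(parms, str) else parms)
    known = {"pbeta", "N", "delta", "alpha", "sigma2_zp"}
    bad = req - known
    if bad:
        raise ValueError(f"unknown parms {sorted(bad)}")
    if "sigma2_zp" in req and not mf_p.has_h:
        raise ValueError("sigma2_zp monitored but mod.p has no ~h term")
    if delta_mode == "fixed":
        req.discard("delta")
        req.discard("alpha")
    return {
        "all": want_all,
        "pbeta": want_all or "pbeta" in req,
        "N": want_all or "N" in req,
        "delta": (want_all or "delta" in req) and delta_mode != "fixed",
        "alpha": (want_all or "alpha" in req) and data_type == "sometimes"
                 and delta_mode != "fixed",
        "sigma2_zp": (want_all or "sigma2_zp" in req) and mf_p.has_h,
    }


def _run_chain_closed(
    obs: ObservedData,
    lmap,
    codes: np.ndarray,
    T: int,
    mf_p,
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
    x = initialize_frequencies(lmap)
    pool = SlotPool.from_frequencies(x, ("zp",))
    n_cap = pool.hist.size
    cfg = SamplerConfig(maxnumbasis=maxnumbasis)
    det = codes > 0
    first0 = det.argmax(axis=1)

    _X_shared = None if mf_p.depends_on_first_capture else build_design(
        mf_p, T, "p", covariates=covariates
    ).X

    def design_for(fc0: np.ndarray) -> np.ndarray:
        if _X_shared is not None:
            return _X_shared
        return build_design(mf_p, T, "p", first_capture=fc0 + 1,
                            covariates=covariates).X

    names_p = build_design(
        mf_p, T, "p",
        first_capture=np.ones(1, dtype=np.int64) if mf_p.depends_on_first_capture else None,
        covariates=covariates,
    ).names
    kp = len(names_p)
    # capture design of a never-detected individual (c and cohort at reference)
    X_capture = build_design(
        mf_p, T, "p",
        first_capture=np.array([T + 1]) if mf_p.depends_on_first_capture else None,
        covariates=covariates,
    ).X[0]

    beta = np.zeros(kp)
    sigma2_zp = 0.25 if mf_p.has_h else 0.0
    if delta_mode == "fixed":
        delta1, delta2, alpha = 1.0, 0.0, 0.0
    else:
        delta1 = delta2 = 0.35
        alpha = {"never": 0.0, "always": 1.0}.get(obs.data_type, 0.5)
    n = int(x.sum())
    pstar = _pstar_fast(X_capture @ beta, sigma2_zp)
    N = update_N(n, pstar, rng)

    beta_scale = _AdaptiveScale(0.3 / np.sqrt(kp))
    z_scale = _AdaptiveScale(0.5, target=0.44)
    s2_scale = _AdaptiveScale(0.5, target=0.44)

    def cell_logprobs(hist_idx: np.ndarray, z: np.ndarray, beta_: np.ndarray) -> np.ndarray:
        m = hist_idx.size
        X = design_for(first0[hist_idx])
        eta = (X if X.shape[0] != 1 else np.broadcast_to(X, (m, T, kp))) @ beta_
        if mf_p.has_h:
            eta = eta + z[:, None]
        p = expit(eta)
        tf = _type_factors(delta1, delta2, alpha)
        cds = codes[hist_idx]
        factors = np.where(cds == 0, 1.0 - p, p * tf[cds])
        return np.log(factors + _EPS).sum(axis=1)

    def log_cells_for_move(hist_idx, zdict):
        return cell_logprobs(hist_idx, zdict["zp"], beta)

    def draw_z(m, rng_):
        return {
            "zp": rng_.normal(0, np.sqrt(sigma2_zp), m) if mf_p.has_h else np.zeros(m)
        }

    def extra_log_target(n_: int) -> float:
        if n_ > N:
            return -np.inf
        return float(
            gammaln(N + 1) - gammaln(n_ + 1) - gammaln(N - n_ + 1)
            + (N - n_) * np.log1p(-pstar)
        )

    rec_rows: list[np.ndarray] = []
    cols: list[str] = []
    rec_slot_hist = np.full((nsave, n_cap), -1, dtype=np.int16) if monitor["all"] else None
    rec_zp = np.zeros((nsave, n_cap)) if monitor["all"] else None
    saved = 0
    acc_counts = {"latent": 0, "beta": 0, "z": 0.0, "sigma2": 0}
    n_z_updates = 0

    for it in range(iters):
        adapting = it < burnin

        # --- latent frequencies (then N, to keep its conditional exact) ---
        x, accepted = latent_step(
            x, lmap, pool, cfg, rng, log_cells_for_move, draw_z, extra_log_target
        )
        acc_counts["latent"] += int(accepted)
        n = int(x.sum())
        N = update_N(n, pstar, rng)

        a_idx = pool.active
        hist_a = pool.hist[a_idx]
        z_a = pool.z["zp"][a_idx]

        # --- detection coefficients: adaptive random-walk MH ---
        beta_prop = beta + beta_scale.scale * rng.standard_normal(kp)
        pstar_prop = _pstar_fast(X_capture @ beta_prop, sigma2_zp)
        def beta_target(b, ps):
            return (
                cell_logprobs(hist_a, z_a, b).sum()
                + (N - n) * np.log1p(-ps)
                - 0.5 * (b @ b) / priors.beta_var
            )
        log_r = beta_target(beta_prop, pstar_prop) - beta_target(beta, pstar)
        if np.log(rng.uniform()) < log_r:
            beta, pstar = beta_prop, pstar_prop
            acc_counts["beta"] += 1
            beta_scale.update(1.0, adapting)
        else:
            beta_scale.update(0.0, adapting)

        # --- individual effects and their variance ---
        if mf_p.has_h and a_idx.size:
            z_prop = z_a + z_scale.scale * rng.standard_normal(a_idx.size)
            lp_cur = cell_logprobs(hist_a, z_a, beta) - 0.5 * z_a**2 / sigma2_zp
            lp_new = cell_logprobs(hist_a, z_prop, beta) - 0.5 * z_prop**2 / sigma2_zp
            acc = np.log(rng.uniform(size=a_idx.size)) < lp_new - lp_cur
            z_a = np.where(acc, z_prop, z_a)
            pool.z["zp"][a_idx] = z_a
            frac = float(acc.mean())
            acc_counts["z"] += frac
            n_z_updates += 1
            z_scale.update(frac, adapting)

            ls2 = np.log(sigma2_zp)
            ls2_prop = ls2 + s2_scale.scale * rng.standard_normal()
            s2_prop = float(np.exp(ls2_prop))
            ps_prop = _pstar_fast(X_capture @ beta, s2_prop)

            def s2_target(s2, ps):
                # half-Cauchy(scale) prior on sigma, Jacobian of log sigma^2
                sig = np.sqrt(s2)
                return (
                    -0.5 * a_idx.size * np.log(s2)
                    - 0.5 * float(z_a @ z_a) / s2
                    + (N - n) * np.log1p(-ps)
                    - np.log(1.0 + s2 / priors.sigma_scale**2)
                    + 0.5 * np.log(s2)  # log|d sigma / d log sigma^2| up to const
                )
            log_r = s2_target(s2_prop, ps_prop) - s2_target(sigma2_zp, pstar)
            if np.log(rng.uniform()) < log_r:
                sigma2_zp = s2_prop
                pstar = ps_prop
                acc_counts["sigma2"] += 1
                s2_scale.update(1.0, adapting)
            else:
                s2_scale.update(0.0, adapting)

        # --- encounter-type probabilities ---
        if delta_mode != "fixed":
            tcounts = encounter_type_counts(x, codes)
            delta1, delta2 = update_delta(tcounts, delta_mode, priors, rng)
            alpha = update_alpha(tcounts, obs.data_type, priors, rng)

        # --- N with refreshed p* ---
        N = update_N(n, pstar, rng)

        if it >= burnin and (it - burnin) % thin == 0:
            vals, cols = _record_closed(
                monitor, beta, N, delta1, delta2, alpha, sigma2_zp, names_p
            )
            rec_rows.append(vals)
            if monitor["all"]:
                rec_slot_hist[saved] = pool.hist.astype(np.int16)
                zrec = pool.z["zp"].copy()
                if mf_p.has_h:
                    inact = pool.hist < 0
                    zrec[inact] = rng.normal(
                        0, np.sqrt(sigma2_zp), int(inact.sum())
                    )
                rec_zp[saved] = zrec
            saved += 1

    draws = np.asarray(rec_rows)
    acc = {
        "latent": acc_counts["latent"] / iters,
        "beta": acc_counts["beta"] / iters,
        "z": acc_counts["z"] / max(n_z_updates, 1),
        "sigma2": acc_counts["sigma2"] / iters if mf_p.has_h else None,
    }
    ext = {
        "slot_hist": rec_slot_hist if monitor["all"] else np.zeros((0, 0), dtype=np.int16),
        "zp": rec_zp if monitor["all"] else np.zeros((0, 0)),
    }
    return draws, cols, ext, acc


def _record_closed(monitor, beta, N, delta1, delta2, alpha, sigma2_zp, names_p):
    vals: list[float] = []
    cols: list[str] = []
    if monitor["pbeta"]:
        vals.extend(beta)
        cols.extend([f"pbeta[{n}]" for n in names_p])
    if monitor["N"]:
        vals.append(float(N))
        cols.append("N")
    if monitor["alpha"]:
        vals.append(alpha)
        cols.append("alpha")
    if monitor["sigma2_zp"]:
        vals.append(sigma2_zp)
        cols.append("sigma2_zp")
    if monitor["delta"]:
        vals.extend([delta1, delta2])
        cols.extend(["delta_1", "delta_2"])
    return np.asarray(vals), cols


def mark_closed(data, mod_p: str = "~1", **kwargs) -> PosteriorSamples:
    """Conventional single-mark closed-population fit (histories over {0,1}).

    Fixes ``delta_1 = 1, delta_2 = 0`` so the two-mark model reduces exactly
    to a conventional Bayesian closed-population abundance model.
    """
    kwargs.setdefault("data_type", "never")
    kwargs.setdefault("parms", ("pbeta", "N"))
    return fit_closed(data, mod_p=mod_p, mod_delta="fixed", **kwargs)
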