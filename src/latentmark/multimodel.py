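"""Bayesian multimodel inference from saved per-model MCMC output.

Models are first fitted individually (with *all* parameters monitored); a
Gibbs sampler then explores the joint space of (model indicator, parameter
blocks).  Each iteration (a) draws the current model's parameter vector --
together with the shared latent block (frequency configuration and, for
closed models, N) -- from that model's stored posterior, (b) draws every
other model's specific parameters from its *pseudoprior* (an independent
moment-matched normal on a transformed scale, fitted to that model's own
stored output), and (c) draws the model indicator from its full
conditional, where each model's score is

    log prior(m) + complete-data loglik_m + log prior_m(specific)
                 - log pseudoprior_m(specific),

evaluated with a numerically stable log-sum-exp.  Indicator visit
frequencies estimate posterior model probabilities; monitored common
parameters are collected from the visited model at each iteration, giving
model-averaged posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .posterior import PosteriorSamples, hpd_and_mode

__all__ = [
    "ModelEntry",
    "MultimodelResult",
    "model_average",
    "summarize_mm",
    "closed_model_entry",
    "cjs_model_entry",
]


# ---------------------------------------------------------------------------
# pseudopriors

_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    # name -> (to unconstrained, back)
    "identity": (lambda v: v, lambda t: t),
    "log": (np.log, np.exp),
    "logit": (logit, expit),
    "logit2": (lambda v: logit(np.clip(2.0 * v, 1e-12, 1 - 1e-12)),
               lambda t: expit(t) / 2.0),
}


@dataclass
class _Pseudoprior:
    """Independent normal pseudoprior on transformed parameters."""

    names: list[str]
    transforms: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, draws: pd.DataFrame, transforms: dict[str, str]) -> "_Pseudoprior":
        names = list(draws.columns)
        trs = [transforms.get(n, "identity") for n in names]
        cols = []
        for n, tr in zip(names, trs):
            fwd = _TRANSFORMS[tr][0]
            cols.append(fwd(np.clip(draws[n].to_numpy(dtype=float), -1e12, 1e12)))
        tmat = np.stack(cols, axis=1) if cols else np.zeros((len(draws), 0))
        mean = tmat.mean(axis=0) if tmat.size else np.zeros(0)
        sd = np.maximum(tmat.std(axis=0, ddof=1) if len(draws) > 1 else np.zeros_like(mean), 1e-6)
        return cls(names, trs, mean, sd)

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        t = self.mean + self.sd * rng.standard_normal(self.mean.size)
        out = {}
        for j, (n, tr) in enumerate(zip(self.names, self.transforms)):
            out[n] = float(_TRANSFORMS[tr][1](t[j]))
        return out

    def logpdf(self, values: dict[str, float]) -> float:
        """Density of the *untransformed* values (includes the Jacobian)."""
        lp = 0.0
        for j, (n, tr) in enumerate(zip(self.names, self.transforms)):
            v = values[n]
            t = float(_TRANSFORMS[tr][0](np.asarray(v)))
            lp += -0.5 * ((t - self.mean[j]) / self.sd[j]) ** 2 - np.log(
                self.sd[j] * np.sqrt(2 * np.pi)
            )
            # Jacobian dt/dv
            if tr == "log":
                lp += -np.log(max(v, 1e-300))
            elif tr == "logit":
                lp += -np.log(max(v * (1 - v), 1e-300))
            elif tr == "logit2":
                u = 2.0 * v
                lp += np.log(2.0) - np.log(max(u * (1 - u), 1e-300))
        return float(lp)


# ---------------------------------------------------------------------------
# model entries

@dataclass
class ModelEntry:
    """One fitted model prepared for multimodel inference.

    ``draws`` holds the stacked post-burn-in draws of all float parameters;
    ``common`` names the columns of the shared block (drawn with the model
    indicator, no pseudoprior); the remaining columns are model-specific.
    ``loglik_fn(common_values, specific_values, slot_hist_row)`` evaluates
    the complete-data log likelihood; ``logprior_fn(specific_values)`` the
    specific block's prior.  ``slot_hist`` (optional) carries the latent
    configuration per stored draw.
    """

    label: str
    draws: pd.DataFrame
    loglik_fn: Callable[[dict, dict, Optional[np.ndarray]], float]
    logprior_fn: Callable[[dict], float]
    common: tuple[str, ...] = ()
    transforms: dict[str, str] = field(default_factory=dict)
    slot_hist: Optional[np.ndarray] = None
    pseudo: Optional[_Pseudoprior] = None
    override_pseudoprior: Optional[_Pseudoprior] = None

    def __post_init__(self) -> None:
        spec_cols = [c for c in self.draws.columns if c not in self.common]
        self._spec_cols = spec_cols
        if self.pseudo is None:
            self.pseudo = self.override_pseudoprior or _Pseudoprior.fit(
                self.draws[spec_cols], self.transforms
            )

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def row(self, r: int) -> tuple[dict, dict, Optional[np.ndarray]]:
        rec = self.draws.iloc[r]
        common = {c: float(rec[c]) for c in self.common}
        spec = {c: float(rec[c]) for c in self._spec_cols}
        sh = self.slot_hist[r] if self.slot_hist is not None else None
        return common, spec, sh


@dataclass
class MultimodelResult:
    """RJMCMC output: indicator chain, probabilities, model-averaged draws."""

    labels: list[str]
    indicator: np.ndarray
    pos_prob: dict[str, float]
    averaged: pd.DataFrame

    def top_model(self) -> str:
        return max(self.pos_prob, key=self.pos_prob.get)


def model_average(
    models: Sequence[ModelEntry],
    modprior: Optional[Sequence[float]] = None,
    monparms: Sequence[str] = ("N",),
    iter: int = 20000,
    burnin: int = 1000,
    seed: Optional[int] = None,
) -> MultimodelResult:
    """Posterior model probabilities and model-averaged draws by RJMCMC.

    ``modprior`` defaults to equal prior model probabilities.  ``monparms``
    must be common to every model's draws.  Visit frequencies of the model
    indicator (after ``burnin``) estimate the posterior model probabilities,
    which sum to one by construction.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("multimodel inference needs >= 2 models")
    n_draw_set = {m.n_draws for m in models}
    if len(n_draw_set) != 1:
        raise ValueError("all models must have the same number of stored draws")
    for m in models:
        missing = [p for p in monparms if p not in m.draws.columns]
        if missing:
            raise ValueError(f"model {m.label!r} is missing monitored {missing}")
    M = len(models)
    prior = np.full(M, 1.0 / M) if modprior is None else np.asarray(modprior, float)
    if prior.size != M or not np.isclose(prior.sum(), 1.0):
        raise ValueError("modprior must have one probability per model, summing to 1")
    rng = np.random.default_rng(seed)

    k = int(rng.integers(M))
    indicator = np.zeros(iter, dtype=np.int64)
    mon_rows = np.zeros((iter, len(monparms)))
    log_prior = np.log(prior + 1e-300)

    for it in range(iter):
        common, spec_k, sh = models[k].row(int(rng.integers(models[k].n_draws)))
        indicator[it] = k
        mon_rows[it] = [common.get(p, spec_k.get(p, np.nan)) for p in monparms]

        scores = np.empty(M)
        for m, entry in enumerate(models):
            spec = spec_k if m == k else entry.pseudo.draw(rng)
            ll = entry.loglik_fn(common, spec, sh)
            scores[m] = (
                log_prior[m]
                + ll
                + entry.logprior_fn(spec)
                - entry.pseudo.logpdf(spec)
            )
        scores -= scores.max()
        w = np.exp(scores)
        w /= w.sum()
        k = int(rng.choice(M, p=w))

    keep = slice(burnin, None)
    ind = indicator[keep]
    counts = np.bincount(ind, minlength=M)
    pos_prob = {m.label: counts[j] / ind.size for j, m in enumerate(models)}
    averaged = pd.DataFrame(mon_rows[keep], columns=list(monparms))
    averaged.insert(0, "model", [models[j].label for j in ind])
    return MultimodelResult(
        labels=[m.label for m in models],
        indicator=ind,
        pos_prob=pos_prob,
        averaged=averaged,
    )


def summarize_mm(
    result: MultimodelResult, prob: float = 0.95
) -> pd.DataFrame:
    """Model-averaged posterior modes and HPD intervals per monitored parameter."""
    rows = {}
    for col in result.averaged.columns:
        if col == "model":
            continue
        draws = result.averaged[col].to_numpy(dtype=float)
        mode, (lo, hi) = hpd_and_mode(draws, prob)
        rows[col] = {"Mode": mode, f"HPDI {prob:.0%} lower": lo,
                     f"HPDI {prob:.0%} upper": hi}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# factories for fitted capture-recapture models

def _require_all(samples: PosteriorSamples) -> None:
    if "slot_hist" not in samples.extras:
        raise ValueError(
            'fit must be run with parms="all" to be used in multimodel inference'
        )


def closed_model_entry(
    samples: PosteriorSamples,
    setup,
    label: Optional[str] = None,
    priors=None,
) -> ModelEntry:
    """Prepare a :func:`~latentmark.closed.fit_closed` result (parms="all").

    The shared block is ``N`` plus the latent configuration; detection
    coefficients, delta/alpha and any heterogeneity parameters are
    model-specific with pseudopriors on suitable transformed scales.
    """
    from scipy.special import gammaln

    from ._engine import Priors
    from .closed import _pstar_fast, _type_factors
    from .design import build_design, parse_formula

    _require_all(samples)
    priors = priors or Priors()
    obs, lmap = setup
    meta = samples.metadata
    mf_p = parse_formula(meta["mod_p"])
    delta_mode = "type" if meta["mod_delta"] == "~type" else "shared"
    data_type = meta["data_type"]
    codes = lmap.codes_matrix
    T = codes.shape[1]
    det = codes > 0
    first0 = det.argmax(axis=1)
    has_h = mf_p.has_h

    names_p = [n for n in samples.names if n.startswith("pbeta[")]
    kp = len(names_p)
    n_cap = samples.extras["slot_hist"].shape[-1]

    flat = samples.to_dataframe().drop(columns=["chain"])
    slot_hist = samples.extras["slot_hist"].reshape(-1, n_cap)
    zp = samples.extras["zp"].reshape(-1, n_cap)
    if has_h:
        for i in range(n_cap):
            flat[f"zp[{i}]"] = zp[:, i]

    X_capture = build_design(
        mf_p, T, "p",
        first_capture=np.array([T + 1]) if mf_p.depends_on_first_capture else None,
        covariates=obs.covariates,
    ).X[0]
    _X_shared = None if mf_p.depends_on_first_capture else build_design(
        mf_p, T, "p", covariates=obs.covariates
    ).X

    def loglik(common: dict, spec: dict, sh: Optional[np.ndarray]) -> float:
        N = int(round(common["N"]))
        active = np.flatnonzero(sh >= 0)
        hist = sh[active].astype(np.int64)
        n = active.size
        if N < n:
            return -np.inf
        beta = np.array([spec[nm] for nm in names_p])
        if delta_mode == "type":
            d1, d2 = spec["delta_1"], spec["delta_2"]
        else:
            d1 = d2 = spec["delta_1"]
        if d1 < 0 or d2 < 0 or d1 + d2 > 1:
            return -np.inf
        a = spec.get("alpha", {"never": 0.0, "always": 1.0}.get(data_type, 0.5))
        s2 = spec.get("sigma2_zp", 0.0)
        if s2 < 0:
            return -np.inf
        if _X_shared is not None:
            X = np.broadcast_to(_X_shared, (n, T, kp))
        else:
            X = build_design(mf_p, T, "p", first_capture=first0[hist] + 1,
                             covariates=obs.covariates).X
        eta = X @ beta
        if has_h:
            eta = eta + np.array([spec[f"zp[{i}]"] for i in active])[:, None]
        p = expit(eta)
        tf = _type_factors(d1, d2, a)
        cds = codes[hist]
        cells = np.log(np.where(cds == 0, 1.0 - p, p * tf[cds]) + 1e-300).sum()
        pstar = _pstar_fast(X_capture @ beta, s2)
        x = np.bincount(hist, minlength=lmap.n_histories)
        log_mult = gammaln(n + 1) - gammaln(x + 1).sum()
        return float(
            cells
            + log_mult
            + gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
            + (N - n) * np.log1p(-min(pstar, 1 - 1e-12))
        )

    def logprior(spec: dict) -> float:
        beta = np.array([spec[nm] for nm in names_p])
        lp = float(-0.5 * (beta @ beta) / priors.beta_var
                   - kp * 0.5 * np.log(2 * np.pi * priors.beta_var))
        if delta_mode == "type":
            d1, d2 = spec["delta_1"], spec["delta_2"]
            if d1 < 0 or d2 < 0 or d1 + d2 > 1:
                return -np.inf
            lp += np.log(2.0)  # Dirichlet(1,1,1) density on the simplex
        else:
            d = spec["delta_1"]
            if not 0 < d < 0.5:
                return -np.inf
            lp += np.log(2.0)  # uniform on (0, 0.5)
        if data_type == "sometimes":
            a = spec.get("alpha", 0.5)
            if not 0 <= a <= 1:
                return -np.inf
            # Beta(1,1): density 1
        if has_h:
            s2 = spec["sigma2_zp"]
            if s2 <= 0:
                return -np.inf
            sig = np.sqrt(s2)
            # half-Cauchy(scale) on sigma, transformed to sigma^2
            lp += (
                np.log(2.0 / (np.pi * priors.sigma_scale))
                - np.log1p(s2 / priors.sigma_scale**2)
                - np.log(2.0 * sig)
            )
            z = np.array([spec[f"zp[{i}]"] for i in range(n_cap)])
            lp += float(
                -0.5 * (z @ z) / s2 - n_cap * 0.5 * np.log(2 * np.pi * s2)
            )
        return lp

    transforms: dict[str, str] = {}
    if delta_mode == "type":
        transforms["delta_1"] = "logit"
        transforms["delta_2"] = "logit"
    else:
        transforms["delta_1"] = "logit2"
        transforms["delta_2"] = "logit2"
    if data_type == "sometimes":
        transforms["alpha"] = "logit"
    if has_h:
        transforms["sigma2_zp"] = "log"

    # delta_2 duplicates delta_1 under the shared model: drop it from the
    # specific block to keep the pseudoprior nondegenerate
    draws = flat
    if delta_mode == "shared" and "delta_2" in draws.columns:
        draws = draws.drop(columns=["delta_2"])

    return ModelEntry(
        label=label or f"p({meta['mod_p']})delta({meta['mod_delta']})",
        draws=draws,
        loglik_fn=loglik,
        logprior_fn=logprior,
        common=("N",),
        transforms=transforms,
        slot_hist=slot_hist,
    )


def cjs_model_entry(
    samples: PosteriorSamples,
    setup,
    label: Optional[str] = None,
    priors=None,
) -> ModelEntry:
    """Prepare a :func:`~latentmark.cjs.fit_cjs` result (parms="all")."""
    from scipy.special import gammaln, ndtr

    from ._engine import Priors
    from .cjs import _type_factors
    from .design import build_design, parse_formula

    _require_all(samples)
    priors = priors or Priors()
    obs, lmap = setup
    meta = samples.metadata
    mf_p = parse_formula(meta["mod_p"])
    mf_phi = parse_formula(meta["mod_phi"])
    delta_mode = "type" if meta["mod_delta"] == "~type" else "shared"
    data_type = meta["data_type"]
    codes = lmap.codes_matrix
    T = codes.shape[1]
    det = codes > 0
    first0 = det.argmax(axis=1)
    last0 = T - 1 - det[:, ::-1].argmax(axis=1)

    names_p = [n for n in samples.names if n.startswith("pbeta[")]
    names_phi = [n for n in samples.names if n.startswith("phibeta[")]
    n_cap = samples.extras["slot_hist"].shape[-1]

    flat = samples.to_dataframe().drop(columns=["chain"])
    slot_hist = samples.extras["slot_hist"].reshape(-1, n_cap)
    if mf_p.has_h:
        zp = samples.extras["zp"].reshape(-1, n_cap)
        for i in range(n_cap):
            flat[f"zp[{i}]"] = zp[:, i]
    if mf_phi.has_h:
        zphi = samples.extras["zphi"].reshape(-1, n_cap)
        for i in range(n_cap):
            flat[f"zphi[{i}]"] = zphi[:, i]

    _Xp_shared = None if mf_p.depends_on_first_capture else build_design(
        mf_p, T, "p", covariates=obs.covariates
    ).X
    _Xphi_shared = None if mf_phi.depends_on_first_capture else build_design(
        mf_phi, T, "phi", covariates=obs.covariates
    ).X

    def loglik(common: dict, spec: dict, sh: Optional[np.ndarray]) -> float:
        active = np.flatnonzero(sh >= 0)
        hist = sh[active].astype(np.int64)
        m = active.size
        beta_p = np.array([spec[nm] for nm in names_p])
        beta_phi = np.array([spec[nm] for nm in names_phi])
        if delta_mode == "type":
            d1, d2 = spec["delta_1"], spec["delta_2"]
        else:
            d1 = d2 = spec["delta_1"]
        if d1 < 0 or d2 < 0 or d1 + d2 > 1:
            return -np.inf
        a = spec.get("alpha", {"never": 0.0, "always": 1.0}.get(data_type, 0.5))
        Xp = _Xp_shared if _Xp_shared is not None else build_design(
            mf_p, T, "p", first_capture=first0[hist] + 1, covariates=obs.covariates
        ).X
        Xphi = _Xphi_shared if _Xphi_shared is not None else build_design(
            mf_phi, T, "phi", first_capture=first0[hist] + 1,
            covariates=obs.covariates
        ).X
        eta_p = (Xp if Xp.shape[0] != 1 else np.broadcast_to(Xp, (m, T, Xp.shape[2]))) @ beta_p
        eta_phi = (Xphi if Xphi.shape[0] != 1 else np.broadcast_to(Xphi, (m, T - 1, Xphi.shape[2]))) @ beta_phi
        if mf_p.has_h:
            eta_p = eta_p + np.array([spec[f"zp[{i}]"] for i in active])[:, None]
        if mf_phi.has_h:
            eta_phi = eta_phi + np.array([spec[f"zphi[{i}]"] for i in active])[:, None]
        p = ndtr(eta_p)
        phi = ndtr(eta_phi)
        tf = _type_factors(d1, d2, a)
        cds = codes[hist]
        C0, L0 = first0[hist], last0[hist]
        occ = np.arange(T)
        inside = (occ[None, :] > C0[:, None]) & (occ[None, :] <= L0[:, None])
        phi_pad = np.concatenate([np.ones((m, 1)), phi], axis=1)
        contrib = np.where(
            cds > 0,
            np.log(p * tf[cds] * phi_pad + 1e-300),
            np.log((1.0 - p) * phi_pad + 1e-300),
        )
        lp = np.log(tf[cds[np.arange(m), C0]] + 1e-300)
        lp = lp + np.where(inside, contrib, 0.0).sum(axis=1)
        chi = np.ones(m)
        for t0 in range(T - 1, 0, -1):
            chi_new = (1.0 - phi[:, t0 - 1]) + phi[:, t0 - 1] * (1.0 - p[:, t0]) * chi
            chi = np.where(L0 < t0, chi_new, chi)
        lp = lp + np.log(chi + 1e-300)
        x = np.bincount(hist, minlength=lmap.n_histories)
        log_mult = gammaln(m + 1) - gammaln(x + 1).sum()
        return float(lp.sum() + log_mult)

    def logprior(spec: dict) -> float:
        lp = 0.0
        for group, names in (("p", names_p), ("phi", names_phi)):
            b = np.array([spec[nm] for nm in names])
            lp += float(-0.5 * (b @ b) / priors.beta_var
                        - b.size * 0.5 * np.log(2 * np.pi * priors.beta_var))
        if delta_mode == "type":
            d1, d2 = spec["delta_1"], spec["delta_2"]
            if d1 < 0 or d2 < 0 or d1 + d2 > 1:
                return -np.inf
            lp += np.log(2.0)
        else:
            d = spec["delta_1"]
            if not 0 < d < 0.5:
                return -np.inf
            lp += np.log(2.0)
        for s2name, zprefix, active_h in (
            ("sigma2_zp", "zp", mf_p.has_h),
            ("sigma2_zphi", "zphi", mf_phi.has_h),
        ):
            if not active_h:
                continue
            s2 = spec[s2name]
            if s2 <= 0:
                return -np.inf
            # CJS variances: Inverse-Gamma(shape, rate) prior
            a, b = priors.sigma2_shape, priors.sigma2_rate
            lp += a * np.log(b) - gammaln(a) - (a + 1) * np.log(s2) - b / s2
            z = np.array([spec[f"{zprefix}[{i}]"] for i in range(n_cap)])
            lp += float(-0.5 * (z @ z) / s2 - n_cap * 0.5 * np.log(2 * np.pi * s2))
        return lp

    transforms: dict[str, str] = {}
    if delta_mode == "type":
        transforms["delta_1"] = "logit"
        transforms["delta_2"] = "logit"
    else:
        transforms["delta_1"] = "logit2"
    if data_type == "sometimes":
        transforms["alpha"] = "logit"
    if mf_p.has_h:
        transforms["sigma2_zp"] = "log"
    if mf_phi.has_h:
        transforms["sigma2_zphi"] = "log"

    draws = flat
    if delta_mode == "shared" and "delta_2" in draws.columns:
        draws = draws.drop(columns=["delta_2"])

    return ModelEntry(
        label=label or f"p({meta['mod_p']})phi({meta['mod_phi']})delta({meta['mod_delta']})",
        draws=draws,
        loglik_fn=loglik,
        logprior_fn=logprior,
        common=(),
        transforms=transforms,
        slot_hist=slot_hist,
    )
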