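"""Posterior sample containers, summaries, diagnostics and derived scales.

The summary layout mirrors the standard MCMC summary for capture-recapture
output: empirical mean and SD per monitored parameter, the naive standard
error ``SD/sqrt(n)``, a time-series (autocorrelation-adjusted) standard
error, and the 2.5/25/50/75/97.5% quantiles.  Highest-posterior-density
intervals and posterior modes are computed empirically: shortest interval
containing the requested mass; kernel-density maximizer (Silverman
bandwidth) for continuous parameters and the most frequent value for
integer-valued ones such as abundance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import gaussian_kde

__all__ = [
    "PosteriorSamples",
    "summarize",
    "diagnostics",
    "hpd_and_mode",
    "hpd_interval",
    "get_probs",
]


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws: ``chains`` has shape (nchains, ndraws, k)."""

    chains: np.ndarray
    names: list[str]
    metadata: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chains = np.asarray(self.chains, dtype=float)
        if self.chains.ndim != 3:
            raise ValueError("chains must have shape (nchains, ndraws, nparams)")
        if self.chains.shape[2] != len(self.names):
            raise ValueError("names must match the parameter dimension")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")

    @property
    def nchains(self) -> int:
        return self.chains.shape[0]

    @property
    def ndraws(self) -> int:
        return self.chains.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: shape (nchains*ndraws, k)."""
        return self.chains.reshape(-1, self.chains.shape[2])

    def param(self, name: str) -> np.ndarray:
        return self.chains[:, :, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stacked(), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(self.nchains), self.ndraws))
        return df

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(
            posterior={n: self.param(n) for n in self.names}
        )

    def subset(self, names: Sequence[str]) -> "PosteriorSamples":
        idx = [self.names.index(n) for n in names]
        return PosteriorSamples(
            self.chains[:, :, idx], list(names), dict(self.metadata)
        )

    def save(self, prefix: str) -> None:
        """Write draws to ``<prefix>_draws.csv`` and metadata to JSON."""
        self.to_dataframe().to_csv(f"{prefix}_draws.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {k: v for k, v in self.metadata.items() if _jsonable(v)}, fh, indent=1
            )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summary table (mean, SD, naive SE, time-series SE, quantiles)."""
    flat = samples.stacked()
    n = flat.shape[0]
    idata = samples.to_inference_data()
    rows = {}
    for j, name in enumerate(samples.names):
        draws = flat[:, j]
        sd = draws.std(ddof=1) if n > 1 else 0.0
        if sd > 0:
            ts_se = float(az.mcse(idata, var_names=[name])[name].values)
        else:
            ts_se = 0.0
        rows[name] = {
            "Mean": draws.mean(),
            "SD": sd,
            "Naive SE": sd / np.sqrt(n),
            "Time-series SE": ts_se,
            "2.5%": np.quantile(draws, 0.025),
            "25%": np.quantile(draws, 0.25),
            "50%": np.quantile(draws, 0.50),
            "75%": np.quantile(draws, 0.75),
            "97.5%": np.quantile(draws, 0.975),
        }
    return pd.DataFrame(rows).T


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Effective sample sizes and (for >= 2 chains) the Gelman-Rubin statistic."""
    idata = samples.to_inference_data()
    ess = az.ess(idata)
    out = pd.DataFrame({"ESS": [float(ess[n].values) for n in samples.names]},
                       index=samples.names)
    if samples.nchains >= 2:
        rhat = az.rhat(idata)
        out["GRB"] = [float(rhat[n].values) for n in samples.names]
    return out


def gelman_rubin(samples: PosteriorSamples) -> pd.DataFrame:
    """Gelman-Rubin statistic; requires at least two chains."""
    if samples.nchains < 2:
        raise ValueError("the Gelman-Rubin diagnostic requires >= 2 chains")
    return diagnostics(samples)[["GRB"]]


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest empirical interval containing ``prob`` of the draws."""
    d = np.sort(np.asarray(draws, dtype=float).ravel())
    n = d.size
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(d[0]), float(d[-1])
    widths = d[m:] - d[: n - m]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + m])


def hpd_and_mode(draws: np.ndarray, prob: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Posterior mode and HPD interval.

    Integer-valued draws get the most frequent value; continuous draws the
    maximizer of a Gaussian KDE with Silverman bandwidth.
    """
    d = np.asarray(draws, dtype=float).ravel()
    interval = hpd_interval(d, prob)
    if np.allclose(d, np.round(d)):
        ints = np.round(d).astype(np.int64)
        vals, counts = np.unique(ints, return_counts=True)
        mode = float(vals[np.argmax(counts)])
    else:
        if d.std() == 0:
            mode = float(d[0])
        else:
            kde = gaussian_kde(d, bw_method="silverman")
            grid = np.linspace(d.min(), d.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
    return mode, interval


def get_probs(
    samples: PosteriorSamples,
    T: int,
    link: str = "probit",
    prefix: str = "pbeta",
    behavioral: bool = False,
    covariates: Optional[pd.DataFrame] = None,
    formula=None,
) -> PosteriorSamples:
    """Per-occasion detection (and recapture) probabilities on the real scale.

    Applies the inverse link (probit for CJS fits, logit for closed fits) to
    the linear predictor at each occasion.  For behavioral-response models
    the capture series ``p[t]`` uses the pre-first-capture design (c = 0)
    and the recapture series ``c[t]`` (t >= 2) the post-first-capture design
    (c = 1); requesting ``c`` from a model without a behavioral term raises.
    Individual effects are evaluated at their population mean (z = 0).
    """
    from .design import build_design, parse_formula  # local import, no cycle

    if formula is None:
        raise ValueError("formula (the model's p formula) is required")
    mf = parse_formula(formula) if isinstance(formula, str) else formula
    has_c = "c" in mf.terms or any("c" in ia for ia in mf.interactions)
    if behavioral and not has_c:
        raise ValueError("recapture probabilities require a behavioral (c) term")
    inv = ndtr if link == "probit" else expit
    beta_names = [n for n in samples.names if n.startswith(prefix + "[")]
    beta = np.stack([samples.param(n) for n in beta_names], axis=-1)  # (c, d, k)

    def series(first_capture_occ: int) -> np.ndarray:
        fc = np.array([first_capture_occ])
        des = build_design(mf, T, target="p",
                           first_capture=fc if mf.depends_on_first_capture else None,
                           covariates=covariates)
        X = des.X[0]  # (T, k)
        return inv(np.einsum("cdk,tk->cdt", beta, X))

    out_cols: list[np.ndarray] = []
    out_names: list[str] = []
    cap = series(T + 1)  # never captured before: c/age columns at reference
    for t in range(1, T + 1):
        out_cols.append(cap[:, :, t - 1])
        out_names.append(f"p[{t}]")
    if has_c:
        rec = series(0)  # first-captured before every occasion: c = 1
        for t in range(2, T + 1):
            out_cols.append(rec[:, :, t - 1])
            out_names.append(f"c[{t}]")
    chains = np.stack(out_cols, axis=-1)
    return PosteriorSamples(chains, out_names, dict(samples.metadata))
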