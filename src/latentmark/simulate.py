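"""Simulate two-mark (or single-mark) encounter histories.

``simdata_cjs`` generates open-population data: every individual enters at
the first occasion, survives each interval with probability ``phi`` (probit
link on ``phibeta`` plus an optional individual effect) and, while alive, is
detected with probability ``p`` (probit link).  ``simdata_closed`` is the
closed-population version (no survival process; logit link for ``p``,
matching the closed model's link).  A detection is of type 1 with
probability ``delta_1``, type 2 with ``delta_2``, and of both types with
``1 - delta_1 - delta_2``, in which case it is simultaneous (code 4) with
probability ``alpha``.  Observed matrices contain the projected type-1 /
type-2 / known records with all-zero rows dropped; with ``delta_1=1,
delta_2=0`` the output is conventional single-mark data over {0,1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, ndtr

from .histories import project_latent

__all__ = ["SimConfig", "simdata_cjs", "simdata_closed", "SimResult"]


@dataclass
class SimConfig:
    """Study conditions for a simulated dataset.

    ``pbeta``/``phibeta`` are link-scale intercepts (scalars) or per-occasion
    vectors; variances ``sigma2_zp``/``sigma2_zphi`` add zero-mean normal
    individual effects on the link scale.  Defaults mirror a moderate
    noninvasive survey: N = 100 individuals, 7 occasions, both-type
    detections possible but not guaranteed to be simultaneous.
    """

    N: int = 100
    noccas: int = 7
    pbeta: Union[float, Sequence[float]] = -0.25
    phibeta: Union[float, Sequence[float]] = 1.0
    delta_1: float = 0.4
    delta_2: float = 0.4
    alpha: float = 0.5
    sigma2_zp: float = 0.0
    sigma2_zphi: float = 0.0
    data_type: str = "sometimes"

    def __post_init__(self) -> None:
        if self.delta_1 < 0 or self.delta_2 < 0 or self.delta_1 + self.delta_2 > 1:
            raise ValueError("need delta_1, delta_2 >= 0 and delta_1 + delta_2 <= 1")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.data_type == "never" and self.alpha != 0:
            raise ValueError('data type "never" requires alpha = 0')
        if self.data_type == "always" and self.alpha != 1:
            raise ValueError('data type "always" requires alpha = 1')
        if self.sigma2_zp < 0 or self.sigma2_zphi < 0:
            raise ValueError("variances must be nonnegative")


@dataclass
class SimResult:
    """Latent truth and the observed encounter matrix it generated."""

    latent_matrix: np.ndarray  # (N, T) codes 0..4, one row per individual
    observed_matrix: np.ndarray  # one row per recorded history
    config: SimConfig = field(repr=False)


def _per_occasion(value, T: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(T, arr[0])
    if arr.size != T:
        raise ValueError(f"expected scalar or length-{T} vector, got {arr.size}")
    return arr


def _encounter_types(
    detected: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Latent codes for the detected entries of a boolean (N, T) array."""
    codes = np.zeros(detected.shape, dtype=np.int64)
    u = rng.uniform(size=detected.shape)
    both = 1.0 - cfg.delta_1 - cfg.delta_2
    codes[detected & (u < cfg.delta_1)] = 1
    codes[detected & (u >= cfg.delta_1) & (u < cfg.delta_1 + cfg.delta_2)] = 2
    both_mask = detected & (u >= cfg.delta_1 + cfg.delta_2)
    simult = rng.uniform(size=detected.shape) < cfg.alpha
    codes[both_mask & simult] = 4
    codes[both_mask & ~simult] = 3
    del both
    return codes


def _project_rows(latent: np.ndarray, data_type: str) -> np.ndarray:
    rows: list[tuple[int, ...]] = []
    for hist in map(tuple, latent.tolist()):
        if not any(hist):
            continue
        t1, t2, kn = project_latent(hist, data_type)
        for rec in (t1, t2, kn):
            if rec is not None:
                rows.append(rec)
    if not rows:
        return np.zeros((0, latent.shape[1]), dtype=np.int64)
    return np.asarray(rows, dtype=np.int64)


def simdata_cjs(
    config: Optional[SimConfig] = None,
    seed: Optional[Union[int, np.random.Generator]] = None,
    **kwargs,
) -> SimResult:
    """Simulate open-population (CJS) two-mark data.

    All individuals enter at occasion 1; survival and detection use the
    probit link, matching the CJS model fitted to such data.  Keyword
    arguments override :class:`SimConfig` fields.
    """
    cfg = config if config is not None else SimConfig(**kwargs)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = cfg.noccas
    p_occ = ndtr(_per_occasion(cfg.pbeta, T))
    phi_occ = ndtr(_per_occasion(cfg.phibeta, T - 1))
    zp = rng.normal(0.0, np.sqrt(cfg.sigma2_zp), size=cfg.N) if cfg.sigma2_zp > 0 else np.zeros(cfg.N)
    zphi = (
        rng.normal(0.0, np.sqrt(cfg.sigma2_zphi), size=cfg.N)
        if cfg.sigma2_zphi > 0
        else np.zeros(cfg.N)
    )
    p_ind = ndtr(_per_occasion(cfg.pbeta, T)[None, :] + zp[:, None])
    phi_ind = ndtr(_per_occasion(cfg.phibeta, T - 1)[None, :] + zphi[:, None])
    del p_occ, phi_occ

    alive = np.ones((cfg.N, T), dtype=bool)
    for t in range(1, T):
        alive[:, t] = alive[:, t - 1] & (rng.uniform(size=cfg.N) < phi_ind[:, t - 1])
    detected = alive & (rng.uniform(size=(cfg.N, T)) < p_ind)
    latent = _encounter_types(detected, cfg, rng)
    return SimResult(latent, _project_rows(latent, cfg.data_type), cfg)


def simdata_closed(
    config: Optional[SimConfig] = None,
    seed: Optional[Union[int, np.random.Generator]] = None,
    **kwargs,
) -> SimResult:
    """Simulate closed-population two-mark data (logit link for detection)."""
    cfg = config if config is not None else SimConfig(**kwargs)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = cfg.noccas
    zp = rng.normal(0.0, np.sqrt(cfg.sigma2_zp), size=cfg.N) if cfg.sigma2_zp > 0 else np.zeros(cfg.N)
    p_ind = expit(_per_occasion(cfg.pbeta, T)[None, :] + zp[:, None])
    detected = rng.uniform(size=(cfg.N, T)) < p_ind
    latent = _encounter_types(detected, cfg, rng)
    return SimResult(latent, _project_rows(latent, cfg.data_type), cfg)
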