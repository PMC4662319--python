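"""Model formulas and design matrices for detection and survival.

Formulas use tilde syntax, e.g. ``~1``, ``~time``, ``~Time+I(Time^2)``,
``~c+h``, ``~time*c``, ``~cov1+h``.  Supported terms:

- ``1``      intercept only (always included)
- ``time``   occasion factor (treatment coding, first occasion reference)
- ``Time``   linear temporal trend, coded 0..nocc-1
- ``I(Time^2)`` quadratic trend
- ``c``      behavioral response: indicator of occasions strictly after the
             individual's (latent) first capture
- ``h``      individual heterogeneity: a zero-mean normal random effect on
             the link scale (adds no fixed-effect column)
- ``age``    factor on time since first capture (CJS)
- ``cohort`` factor on the occasion of first capture (CJS)
- any covariate column name from the per-occasion covariate table

``a*b`` expands to ``a + b + a:b``; ``a:b`` is the elementwise interaction.
Because ``c``, ``age`` and ``cohort`` depend on the latent configuration,
designs containing them are rebuilt whenever latent first-capture times
change; for fixed first captures they are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ModelFormula", "parse_formula", "Design", "build_design", "bin_levels"]


class FormulaError(ValueError):
    pass


_SPECIAL = {"1", "time", "Time", "I(Time^2)", "c", "h", "age", "cohort"}


@dataclass(frozen=True)
class ModelFormula:
    """A parsed model formula: primitive terms plus interaction tuples."""

    formula: str
    terms: tuple[str, ...]  # primitive (non-interaction) terms, no "1"/"h"
    interactions: tuple[tuple[str, str], ...]
    has_h: bool

    @property
    def depends_on_first_capture(self) -> bool:
        names = set(self.terms) | {t for ia in self.interactions for t in ia}
        return bool(names & {"c", "age", "cohort"})

    def __str__(self) -> str:  # pragma: no cover
        return self.formula


def parse_formula(formula: str) -> ModelFormula:
    """Parse a tilde formula string into a :class:`ModelFormula`."""
    raw = formula.strip()
    body = raw[1:] if raw.startswith("~") else raw
    body = body.strip()
    if not body:
        raise FormulaError(f"empty formula {formula!r}")
    pieces = [p.strip() for p in body.split("+")]
    terms: list[str] = []
    interactions: list[tuple[str, str]] = []
    has_h = False
    for piece in pieces:
        if not piece:
            raise FormulaError(f"malformed formula {formula!r}")
        if "*" in piece and not piece.startswith("I("):
            a, b = (s.strip() for s in piece.split("*", 1))
            for t in (a, b):
                if t not in terms and t != "1":
                    terms.append(t)
            interactions.append((a, b))
        elif ":" in piece and not piece.startswith("I("):
            a, b = (s.strip() for s in piece.split(":", 1))
            interactions.append((a, b))
        elif piece == "h":
            if has_h:
                raise FormulaError("h may appear at most once")
            has_h = True
        elif piece == "1":
            continue
        else:
            if piece not in terms:
                terms.append(piece)
    for a, b in interactions:
        if "h" in (a, b):
            raise FormulaError("h cannot enter interactions")
    return ModelFormula(
        formula=raw if raw.startswith("~") else "~" + raw,
        terms=tuple(terms),
        interactions=tuple(interactions),
        has_h=has_h,
    )


def bin_levels(levels: Sequence[int], bins: Sequence[Sequence[int]]) -> dict[int, int]:
    """Map each level to its bin index; ``bins`` must partition ``levels``."""
    flat = [lv for b in bins for lv in b]
    if sorted(flat) != sorted(levels):
        raise FormulaError(
            f"bins {bins} do not partition levels {sorted(levels)}"
        )
    return {lv: k for k, b in enumerate(bins) for lv in b}


@dataclass
class Design:
    """Design matrix for one target (p or phi).

    ``X`` has shape ``(n, nocc, k)`` when any term depends on first capture,
    else ``(1, nocc, k)`` (broadcastable across individuals).  ``nocc`` is
    ``T`` for detection and ``T-1`` for survival (row ``t`` of the survival
    design governs the interval from occasion ``t`` to ``t+1``).
    """

    X: np.ndarray
    names: list[str]
    has_h: bool
    target: str
    formula: ModelFormula = field(repr=False)

    @property
    def k(self) -> int:
        return self.X.shape[2]


def _factor_columns(values: np.ndarray, levels: list[int], label: str,
                    bins: Optional[Sequence[Sequence[int]]]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies (first level/bin is the reference)."""
    if bins is not None:
        mapping = bin_levels(levels, bins)
        coded = np.vectorize(lambda v: mapping.get(int(v), 0))(values)
        nlev = len(bins)
        names = [f"{label}[bin{k}]" for k in range(1, nlev)]
    else:
        mapping = {lv: k for k, lv in enumerate(levels)}
        coded = np.vectorize(lambda v: mapping.get(int(v), 0))(values)
        nlev = len(levels)
        names = [f"{label}[{lv}]" for lv in levels[1:]]
    cols = np.stack([(coded == k).astype(float) for k in range(1, nlev)], axis=-1) \
        if nlev > 1 else np.zeros(values.shape + (0,))
    return cols, names


def build_design(
    formula: ModelFormula | str,
    T: int,
    target: str = "p",
    first_capture: Optional[np.ndarray] = None,
    covariates: Optional[pd.DataFrame] = None,
    age_bins: Optional[Sequence[Sequence[int]]] = None,
    cohort_bins: Optional[Sequence[Sequence[int]]] = None,
) -> Design:
    """Build the per-individual, per-occasion design matrix for one target.

    ``first_capture`` is the 1-based first-capture occasion per latent
    individual (required for ``c``/``age``/``cohort``).  ``covariates`` is a
    ``T``-row table of temporal covariates; for the survival target its first
    ``T-1`` rows are used.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if target not in ("p", "phi"):
        raise FormulaError("target must be 'p' or 'phi'")
    nocc = T if target == "p" else T - 1
    if nocc < 1:
        raise FormulaError("need at least 2 occasions for survival design")
    needs_fc = formula.depends_on_first_capture
    if needs_fc:
        if first_capture is None:
            raise FormulaError(
                f"formula {formula.formula} needs first-capture occasions"
            )
        fc = np.asarray(first_capture, dtype=np.int64)
        n = fc.shape[0]
    else:
        fc = None
        n = 1
    occ = np.arange(1, nocc + 1)  # 1-based occasion / interval label
    occ_grid = np.broadcast_to(occ, (n, nocc))

    def primitive(term: str) -> tuple[np.ndarray, list[str]]:
        if term == "time":
            return _factor_columns(occ_grid, list(occ), "time", None)
        if term == "Time":
            col = np.broadcast_to((occ - 1).astype(float), (n, nocc))[..., None]
            return col, ["Time"]
        if term == "I(Time^2)":
            col = np.broadcast_to(((occ - 1).astype(float)) ** 2, (n, nocc))[..., None]
            return col, ["I(Time^2)"]
        if term == "c":
            col = (occ_grid > fc[:, None]).astype(float)[..., None]
            return col, ["c"]
        if term == "age":
            if target == "p":
                age = occ_grid - fc[:, None]
            else:
                age = occ_grid - fc[:, None] + 1  # age at the end of interval t
            age = np.clip(age, 0, T - 1)
            return _factor_columns(age, list(range(1, T)), "age", age_bins)
        if term == "cohort":
            coh = np.broadcast_to(fc[:, None], (n, nocc))
            return _factor_columns(coh, list(range(1, T + 1)), "cohort", cohort_bins)
        if covariates is not None and term in covariates.columns:
            vals = covariates[term].to_numpy(dtype=float)[:nocc]
            col = np.broadcast_to(vals, (n, nocc))[..., None]
            return col, [term]
        raise FormulaError(f"unknown term {term!r} in formula {formula.formula}")

    blocks = [np.ones((n, nocc, 1)), ]
    names = ["(Intercept)"]
    built: dict[str, tuple[np.ndarray, list[str]]] = {}
    for term in formula.terms:
        cols, nm = primitive(term)
        built[term] = (cols, nm)
        blocks.append(cols)
        names.extend(nm)
    for a, b in formula.interactions:
        ca, na = built.get(a) or primitive(a)
        cb, nb = built.get(b) or primitive(b)
        inter = ca[..., :, None] * cb[..., None, :]
        inter = inter.reshape(inter.shape[0], inter.shape[1], -1)
        blocks.append(inter)
        names.extend([f"{x}:{y}" for x in na for y in nb])
    X = np.concatenate(blocks, axis=2)
    return Design(X=X, names=names, has_h=formula.has_h, target=target, formula=formula)
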