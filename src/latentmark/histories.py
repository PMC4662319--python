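"""Latent and observed encounter histories for two-mark capture-recapture.

With two mark types that cannot be matched across individuals (e.g. left- and
right-sided photographs), the true ("latent") encounter history of an
individual is a length-``T`` vector with occasion codes

===== =======================================================
code  meaning
===== =======================================================
0     not detected
1     detected by mark type 1 only
2     detected by mark type 2 only
3     detected by both types, not simultaneously
4     detected by both types simultaneously (identity known)
===== =======================================================

A latent history splits into the records an observer actually gets to see:
a type-1 history over {0,1}, a type-2 history over {0,2}, or -- when a
simultaneous (code 4) detection occurred or the identity was externally
confirmed -- a fully "known" history.  This module encodes/decodes latent
histories, projects them onto observed records, classifies and aggregates a
raw observed matrix, and builds the linear system linking latent-history
frequencies ``x`` to observed record counts (``A^T x = counts``) together
with an integer basis of the null space of ``A^T`` used for MCMC moves on
the feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DATA_TYPES",
    "allowed_codes",
    "encode_history",
    "decode_index",
    "enumerate_latent_histories",
    "project_latent",
    "LatentHistory",
    "ObservedData",
    "LatentMap",
    "process_data",
    "initialize_frequencies",
]

DATA_TYPES = ("never", "sometimes", "always")

_ALLOWED = {
    "never": frozenset({0, 1, 2, 3}),
    "sometimes": frozenset({0, 1, 2, 3, 4}),
    "always": frozenset({0, 1, 2, 4}),
}


class HistoryError(ValueError):
    """Raised for malformed encounter histories or inconsistent inputs."""


def _check_data_type(data_type: str) -> str:
    if data_type not in DATA_TYPES:
        raise HistoryError(
            f"data_type must be one of {DATA_TYPES}, got {data_type!r}"
        )
    return data_type


def allowed_codes(data_type: str) -> frozenset[int]:
    """Occasion codes admissible under a data type.

    "never" forbids simultaneous detections (code 4, alpha = 0); "always"
    forbids nonsimultaneous both-type detections (code 3, alpha = 1);
    "sometimes" allows all five codes (0 < alpha < 1).
    """
    return _ALLOWED[_check_data_type(data_type)]


def encode_history(codes: Sequence[int]) -> int:
    """Base-5 index ``j = 1 + sum_t codes[t] * 5^(T-t)`` of a latent history.

    Occasions are 1-based; the all-zero history has index 1 and indices run
    to ``5**T``.
    """
    codes = tuple(int(c) for c in codes)
    if len(codes) < 1:
        raise HistoryError("history must have at least one occasion")
    if any(c < 0 or c > 4 for c in codes):
        raise HistoryError(f"history codes must be in 0..4, got {codes}")
    j = 1
    T = len(codes)
    for t, c in enumerate(codes, start=1):
        j += c * 5 ** (T - t)
    return j


def decode_index(j: int, T: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_history` for a given number of occasions."""
    j = int(j)
    if T < 1:
        raise HistoryError("T must be >= 1")
    if not 1 <= j <= 5**T:
        raise HistoryError(f"index {j} out of range 1..5^{T}")
    rem = j - 1
    codes = []
    for t in range(T):
        power = 5 ** (T - 1 - t)
        codes.append(rem // power)
        rem %= power
    return tuple(codes)


def enumerate_latent_histories(T: int, data_type: str) -> list[tuple[int, ...]]:
    """All latent histories admissible under a data type, in index order.

    Includes the all-zero history; there are ``5**T`` histories for
    "sometimes" and ``4**T`` for "never" or "always".
    """
    allowed = sorted(allowed_codes(data_type))
    out: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...]) -> None:
        if len(prefix) == T:
            out.append(prefix)
            return
        for c in allowed:
            rec(prefix + (c,))

    rec(())
    return out


def project_latent(
    codes: Sequence[int], data_type: str = "sometimes"
) -> tuple[
    Optional[tuple[int, ...]], Optional[tuple[int, ...]], Optional[tuple[int, ...]]
]:
    """Observed records generated by one individual with latent history `codes`.

    Returns ``(type1_record, type2_record, known_record)``; entries are
    ``None`` when no record of that kind is produced.  A history containing a
    simultaneous detection (code 4) is observable in full and yields only a
    known record.  Otherwise codes {1,3} map to 1 in the type-1 record and
    codes {2,3} map to 2 in the type-2 record; all-zero records are dropped.
    """
    allowed = allowed_codes(data_type)
    codes = tuple(int(c) for c in codes)
    bad = set(codes) - allowed
    if bad:
        raise HistoryError(
            f"codes {sorted(bad)} not admissible under data type {data_type!r}"
        )
    if 4 in codes:
        return None, None, codes
    t1 = tuple(1 if c in (1, 3) else 0 for c in codes)
    t2 = tuple(2 if c in (2, 3) else 0 for c in codes)
    return (t1 if any(t1) else None, t2 if any(t2) else None, None)


@dataclass(frozen=True)
class LatentHistory:
    """A latent encounter history together with its base-5 index."""

    codes: tuple[int, ...]
    index_j: int = field(default=0)

    def __post_init__(self) -> None:
        j = encode_history(self.codes)
        if self.index_j == 0:
            object.__setattr__(self, "index_j", j)
        elif self.index_j != j:
            raise HistoryError(
                f"index_j={self.index_j} inconsistent with codes (expected {j})"
            )

    @property
    def T(self) -> int:
        return len(self.codes)


@dataclass
class ObservedData:
    """Recorded encounter histories, split by record class.

    ``type1_histories`` / ``type2_histories`` / ``known_histories`` preserve
    the input rows (duplicates included, order of first appearance); counts
    ``n1``, ``n2``, ``n_known`` are the respective row counts.
    """

    type1_histories: list[tuple[int, ...]]
    type2_histories: list[tuple[int, ...]]
    known_histories: list[tuple[int, ...]]
    data_type: str
    known_flags: Optional[np.ndarray] = None
    covariates: Optional[pd.DataFrame] = None

    @property
    def n1(self) -> int:
        return len(self.type1_histories)

    @property
    def n2(self) -> int:
        return len(self.type2_histories)

    @property
    def n_known(self) -> int:
        return len(self.known_histories)

    @property
    def T(self) -> int:
        for rows in (self.type1_histories, self.type2_histories, self.known_histories):
            if rows:
                return len(rows[0])
        raise HistoryError("no observed histories")


@dataclass
class LatentMap:
    """Latent-to-observed constraint system.

    ``histories`` lists the admissible latent histories (known-pinned rows
    first is *not* guaranteed; use ``is_known``); row ``h`` of the 0/1 matrix
    ``A`` gives, per observed record class (column), how many records of that
    class one individual with latent history ``h`` generates.  A frequency
    vector ``x >= 0`` is feasible iff ``A^T x = observed_counts``.  ``basis``
    spans the integer null space of ``A^T``; adding any signed combination of
    basis vectors to a feasible ``x`` preserves the observed counts.
    """

    histories: list[tuple[int, ...]]
    A: np.ndarray
    observed_counts: np.ndarray
    class_labels: list[tuple[str, tuple[int, ...]]]
    basis: np.ndarray  # (n_basis, H) integer matrix; may have 0 rows
    data_type: str
    is_known: np.ndarray  # bool per history: frequency pinned by a known class

    @property
    def T(self) -> int:
        return len(self.histories[0])

    @property
    def n_histories(self) -> int:
        return len(self.histories)

    @property
    def codes_matrix(self) -> np.ndarray:
        return np.asarray(self.histories, dtype=np.int64)

    def is_feasible(self, x: np.ndarray) -> bool:
        x = np.asarray(x)
        return bool(np.all(x >= 0) and np.array_equal(self.A.T @ x, self.observed_counts))


def _classify_row(row: tuple[int, ...], flagged: bool, data_type: str) -> str:
    vals = set(row) - {0}
    if not vals:
        raise HistoryError("all-zero row: every recorded history must contain a detection")
    bad = set(row) - allowed_codes(data_type)
    if bad:
        raise HistoryError(
            f"row {row} contains codes {sorted(bad)} inadmissible under {data_type!r}"
        )
    if flagged or 4 in vals:
        return "known"
    if vals == {1}:
        return "type1"
    if vals == {2}:
        return "type2"
    raise HistoryError(
        f"row {row} mixes encounter types without a known flag; "
        "rows must be over {0,1}, over {0,2}, contain a 4, or be flagged known"
    )


def _merge_pair(
    t1: Optional[tuple[int, ...]], t2: Optional[tuple[int, ...]]
) -> tuple[int, ...]:
    """Latent history whose projection is exactly the records ``(t1, t2)``."""
    if t1 is None:
        assert t2 is not None
        return t2
    if t2 is None:
        return t1
    return tuple(
        3 if (a == 1 and b == 2) else (1 if a == 1 else b) for a, b in zip(t1, t2)
    )


def process_data(
    raw_matrix,
    data_type: str,
    known_flags: Optional[Sequence[bool]] = None,
    covariates: Optional[pd.DataFrame] = None,
) -> tuple[ObservedData, LatentMap]:
    """Classify and aggregate an observed encounter matrix; build the LatentMap.

    Rows of ``raw_matrix`` (array, DataFrame or nested sequence; columns =
    occasions) are classified automatically as type-1 ({0,1}), type-2 ({0,2})
    or known (contains a 4, or flagged via ``known_flags``); row order is
    unimportant.  Admissible latent histories are enumerated conditional on
    the observed record classes: every unknown latent history is a merge of
    at most one observed type-1 class and one type-2 class (under "always",
    only non-overlapping merges, since co-detection would have been
    simultaneous and hence known).  Known records pin their own latent
    history's frequency.  Returns the per-row :class:`ObservedData` and the
    aggregated :class:`LatentMap`.
    """
    _check_data_type(data_type)
    if isinstance(raw_matrix, pd.DataFrame):
        mat = raw_matrix.to_numpy()
    else:
        mat = np.asarray(raw_matrix)
    if mat.size == 0:
        raise HistoryError("empty encounter matrix")
    if mat.ndim != 2:
        raise HistoryError("encounter matrix must be 2-dimensional")
    if not np.issubdtype(mat.dtype, np.number):
        raise HistoryError("encounter matrix must be numeric")
    if np.any(mat != np.floor(mat)):
        raise HistoryError("encounter matrix must contain integer codes")
    mat = mat.astype(np.int64)
    n_rows, T = mat.shape
    if known_flags is None:
        flags = np.zeros(n_rows, dtype=bool)
    else:
        flags = np.asarray(known_flags, dtype=bool)
        if flags.shape != (n_rows,):
            raise HistoryError("known_flags must have one entry per row")
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        if len(covariates) != T:
            raise HistoryError(
                f"covariate table must have T={T} rows, got {len(covariates)}"
            )

    type1: list[tuple[int, ...]] = []
    type2: list[tuple[int, ...]] = []
    known: list[tuple[int, ...]] = []
    for row, fl in zip(map(tuple, mat.tolist()), flags):
        kind = _classify_row(row, bool(fl), data_type)
        {"type1": type1, "type2": type2, "known": known}[kind].append(row)

    obs = ObservedData(
        type1_histories=type1,
        type2_histories=type2,
        known_histories=known,
        data_type=data_type,
        known_flags=flags,
        covariates=covariates,
    )
    return obs, build_latent_map(obs)


def _distinct_with_counts(
    rows: list[tuple[int, ...]]
) -> tuple[list[tuple[int, ...]], list[int]]:
    classes: list[tuple[int, ...]] = []
    counts: dict[tuple[int, ...], int] = {}
    for r in rows:
        if r not in counts:
            classes.append(r)
            counts[r] = 0
        counts[r] += 1
    return classes, [counts[c] for c in classes]


def build_latent_map(obs: ObservedData) -> LatentMap:
    """Enumerate admissible latent histories and the constraint system.

    The enumeration conditions on the observed record classes: latent
    histories whose projection would include an unobserved record class can
    never have positive frequency and are excluded, as is the all-zero
    history (undetected individuals are handled by the abundance parameter,
    not by the latent frequency vector).
    """
    t1_classes, t1_counts = _distinct_with_counts(obs.type1_histories)
    t2_classes, t2_counts = _distinct_with_counts(obs.type2_histories)
    kn_classes, kn_counts = _distinct_with_counts(obs.known_histories)

    n1c, n2c, nkc = len(t1_classes), len(t2_classes), len(kn_classes)
    n_classes = n1c + n2c + nkc
    class_labels = (
        [("type1", c) for c in t1_classes]
        + [("type2", c) for c in t2_classes]
        + [("known", c) for c in kn_classes]
    )
    observed_counts = np.array(t1_counts + t2_counts + kn_counts, dtype=np.int64)

    histories: list[tuple[int, ...]] = []
    rows: list[np.ndarray] = []
    is_known: list[bool] = []
    # singleton merges (one record explained by one latent individual)
    for k, c in enumerate(t1_classes):
        r = np.zeros(n_classes, dtype=np.int64)
        r[k] = 1
        histories.append(c)
        rows.append(r)
        is_known.append(False)
    for k, c in enumerate(t2_classes):
        r = np.zeros(n_classes, dtype=np.int64)
        r[n1c + k] = 1
        histories.append(c)
        rows.append(r)
        is_known.append(False)
    # full merges: one latent individual explaining a type-1 and a type-2 record
    pair_index: list[tuple[int, int]] = []
    for a, ca in enumerate(t1_classes):
        for b, cb in enumerate(t2_classes):
            overlap = any(x == 1 and y == 2 for x, y in zip(ca, cb))
            if overlap and obs.data_type == "always":
                continue  # co-detection would have been simultaneous, hence known
            r = np.zeros(n_classes, dtype=np.int64)
            r[a] = 1
            r[n1c + b] = 1
            histories.append(_merge_pair(ca, cb))
            rows.append(r)
            is_known.append(False)
            pair_index.append((a, b))
    # known histories: frequency pinned at the known count
    for k, c in enumerate(kn_classes):
        r = np.zeros(n_classes, dtype=np.int64)
        r[n1c + n2c + k] = 1
        histories.append(c)
        rows.append(r)
        is_known.append(True)

    H = len(histories)
    A = np.vstack(rows) if rows else np.zeros((0, n_classes), dtype=np.int64)

    # Integer null-space basis of A^T: one "merge move" per full pair,
    # e_(a,b) - e_(a,.) - e_(.,b).  These generate the whole integer kernel:
    # clearing the pair coordinates of any kernel vector leaves a vector
    # supported on singleton/known histories, whose A^T columns are distinct
    # unit vectors, so it must vanish.
    n_pairs = len(pair_index)
    basis = np.zeros((n_pairs, H), dtype=np.int64)
    for m, (a, b) in enumerate(pair_index):
        basis[m, n1c + n2c + m] = 1  # pair rows follow the singleton rows in order
        basis[m, a] = -1
        basis[m, n1c + b] = -1

    return LatentMap(
        histories=histories,
        A=A,
        observed_counts=observed_counts,
        class_labels=class_labels,
        basis=basis,
        data_type=obs.data_type,
        is_known=np.array(is_known, dtype=bool),
    )


def initialize_frequencies(lmap: LatentMap) -> np.ndarray:
    """The "no-match" feasible starting point.

    Every observed record is attributed to its own latent individual: the
    frequency of each singleton latent history equals its record count and
    all full-merge frequencies are zero.  Known frequencies equal the known
    counts.  Always feasible.
    """
    x = np.zeros(lmap.n_histories, dtype=np.int64)
    col_of_row = lmap.A.argmax(axis=1)
    row_is_singleton = lmap.A.sum(axis=1) == 1
    for cls in range(len(lmap.observed_counts)):
        owners = np.flatnonzero(row_is_singleton & (col_of_row == cls))
        assert owners.size >= 1
        x[owners[0]] = lmap.observed_counts[cls]
    assert lmap.is_feasible(x)
    return x
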