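"""Inter-observer agreement statistics for timed behavioral coding.

Two chance-corrected kappas in the style of sequential-analysis software
(GSEQ) are provided alongside the plain Cohen's kappa and the intraclass
correlation:

* :func:`time_unit_kappa` — the session is discretized into fixed time
  units; a unit of one coder agrees when the other coder holds the same
  code in some unit within a tolerance (default ±1 s).  The tolerance rule
  is applied symmetrically (each coder's units are checked against the
  other's) and the resulting agreement matrix yields kappa.
* :func:`event_alignment_kappa` — the two coders' event sequences are
  aligned globally by dynamic programming; two events may align when their
  onsets are within a tolerance (default 2 s) and they overlap at least 80%
  of the shorter event's duration.  Aligned pairs are tallied by code;
  unmatched events are tallied against a nil code.
* :func:`cohens_kappa` — standard unweighted kappa on paired labels
  (per-segment touch codes).
* :func:`icc_two_way_mixed` — two-way mixed-model intraclass correlation,
  single measures; consistency ICC(3,1) by default, absolute agreement by
  flag.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import UndefinedStatisticError

__all__ = [
    "time_unit_kappa",
    "event_alignment_kappa",
    "cohens_kappa",
    "icc_two_way_mixed",
]

NIL = "<nil>"


def _kappa_from_matrix(matrix: pd.DataFrame) -> float:
    """Cohen's kappa from a square agreement matrix (rows = coder A)."""
    m = matrix.to_numpy(dtype=float)
    total = m.sum()
    p_o = np.trace(m) / total
    p_e = float(m.sum(axis=1) @ m.sum(axis=0)) / total**2
    if p_e >= 1.0 - 1e-12:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def _tally(codes: Sequence[str]) -> pd.DataFrame:
    codes = sorted(set(codes))
    return pd.DataFrame(0.0, index=codes, columns=codes)


def time_unit_kappa(
    a: Sequence[str],
    b: Sequence[str],
    tolerance_s: float = 1.0,
    unit_s: float = 1.0,
) -> tuple[float, float]:
    """Tolerance time-unit kappa and raw percent agreement.

    ``a`` and ``b`` are per-unit code sequences of equal length (one label
    per ``unit_s`` seconds).  A unit agrees when the other coder holds the
    same code within ±``tolerance_s``.  With ``tolerance_s = 0`` this
    reduces exactly to Cohen's kappa on the unit labels.

    Returns ``(kappa, percent_agreement)``; kappa is NaN when the marginals
    are degenerate (a single code everywhere), agreement is still returned.
    """
    if len(a) != len(b):
        raise ValueError("coder sequences must have equal length")
    if len(a) == 0:
        raise UndefinedStatisticError("empty sequences")
    tol = int(round(tolerance_s / unit_s))
    n = len(a)
    matrix = _tally(list(a) + list(b))

    def tolerant_match(x, y, i) -> bool:
        lo, hi = max(0, i - tol), min(n, i + tol + 1)
        return any(y[j] == x[i] for j in range(lo, hi))

    agreements = 0
    # Symmetric tally: each coder's units checked against the other's.
    for x, y in ((a, b), (b, a)):
        for i in range(n):
            if tolerant_match(x, y, i):
                matrix.loc[x[i], x[i]] += 1
                agreements += 1
            else:
                # disagreement recorded at the co-occurring labels
                matrix.loc[a[i], b[i]] += 1
    percent = 100.0 * agreements / (2 * n)
    return _kappa_from_matrix(matrix), percent


def _events_may_align(ea, eb, tolerance_s: float, min_overlap: float) -> bool:
    code_a, on_a, off_a = ea
    code_b, on_b, off_b = eb
    if abs(on_a - on_b) > tolerance_s:
        return False
    shorter = min(off_a - on_a, off_b - on_b)
    overlap = min(off_a, off_b) - max(on_a, on_b)
    if shorter <= 0:
        # durationless events: the onset tolerance is the whole criterion
        return overlap >= 0 or abs(on_a - on_b) <= tolerance_s
    return overlap >= min_overlap * shorter


def event_alignment_kappa(
    a_events: Sequence[tuple[str, float, float]],
    b_events: Sequence[tuple[str, float, float]],
    tolerance_s: float = 2.0,
    min_overlap: float = 0.8,
) -> tuple[float, float]:
    """Event-alignment kappa and percent agreement.

    Events are ``(code, onset_s, offset_s)`` tuples sorted by onset.  A
    global monotone alignment is found by dynamic programming, scoring 2
    for an aligned same-code pair, 1 for an aligned different-code pair and
    0 for an unmatched event; alignment of a pair is only permitted when
    onsets are within ``tolerance_s`` and the temporal overlap covers at
    least ``min_overlap`` of the shorter event.
    """
    if not a_events and not b_events:
        raise UndefinedStatisticError("both event sequences empty")
    na, nb = len(a_events), len(b_events)
    score = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best = max(score[i - 1, j], score[i, j - 1])
            if _events_may_align(a_events[i - 1], b_events[j - 1], tolerance_s, min_overlap):
                match = 2.0 if a_events[i - 1][0] == b_events[j - 1][0] else 1.0
                best = max(best, score[i - 1, j - 1] + match)
            score[i, j] = best

    # traceback (prefer diagonal, then consuming from A)
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        if _events_may_align(a_events[i - 1], b_events[j - 1], tolerance_s, min_overlap):
            match = 2.0 if a_events[i - 1][0] == b_events[j - 1][0] else 1.0
            if score[i, j] == score[i - 1, j - 1] + match:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if score[i, j] == score[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()

    codes = [e[0] for e in a_events] + [e[0] for e in b_events] + [NIL]
    matrix = _tally(codes)
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    agreements = 0
    for i, j in pairs:
        ca, cb = a_events[i][0], b_events[j][0]
        matrix.loc[ca, cb] += 1
        agreements += ca == cb
    for i in range(na):
        if i not in matched_a:
            matrix.loc[a_events[i][0], NIL] += 1
    for j in range(nb):
        if j not in matched_b:
            matrix.loc[NIL, b_events[j][0]] += 1
    total = matrix.to_numpy().sum()
    percent = 100.0 * agreements / total
    return _kappa_from_matrix(matrix), percent


def cohens_kappa(a_labels: Sequence[str], b_labels: Sequence[str]) -> float:
    """Standard unweighted Cohen's kappa on paired label sequences."""
    from sklearn.metrics import cohen_kappa_score

    if len(a_labels) != len(b_labels):
        raise ValueError("label sequences must have equal length")
    if len(a_labels) == 0:
        raise UndefinedStatisticError("empty label sequences")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(cohen_kappa_score(list(a_labels), list(b_labels)))


def icc_two_way_mixed(scores: np.ndarray, kind: str = "consistency") -> float:
    """Two-way mixed-model ICC, single measures, raters × targets.

    ``kind="consistency"`` gives ICC(3,1):
    (MS_targets − MS_error) / (MS_targets + (k−1)·MS_error); ``"agreement"``
    gives the absolute-agreement single-measures ICC.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 raters and >=2 targets")
    if np.isnan(scores).any():
        raise ValueError("missing cells not supported")
    if np.ptp(scores) == 0:
        raise UndefinedStatisticError("constant ratings: ICC undefined")

    import pingouin as pg

    k, n = scores.shape
    long = pd.DataFrame(
        {
            "rater": np.repeat(np.arange(k), n),
            "target": np.tile(np.arange(n), k),
            "score": scores.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
    icc_type = "ICC(C,1)" if kind == "consistency" else "ICC(A,1)"
    value = float(table.loc[icc_type, "ICC"])
    if not np.isfinite(value):
        raise UndefinedStatisticError("ICC undefined for this matrix")
    return value
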