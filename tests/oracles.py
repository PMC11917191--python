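"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — quadratic scans, exhaustive
enumeration, textbook closed forms — and shares no code with the
implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_contingent(mother_events, infant_events, gaze_intervals,
                           w_ms=1000, inclusive_end=True, reuse_maternal=True):
    """Quadratic scan over all (infant, maternal) event pairs.

    Events are objects with .onset_ms/.offset_ms/.modality; gaze_intervals a
    list of (start, end).  Returns sorted (infant_idx, mother_idx) pairs into
    the gaze-filtered, onset-ordered lists.
    """

    def in_gaze(t):
        return any(s <= t < e for s, e in gaze_intervals)

    inf = [e for e in infant_events if in_gaze(e.onset_ms)]
    mot = [e for e in mother_events if in_gaze(e.onset_ms)]

    pairs = []
    consumed = set()
    k = 0
    while k < len(inf):
        onset = inf[k].onset_ms
        group = [g for g in range(len(inf)) if inf[g].onset_ms == onset]
        group_hits = []
        for gi in group:
            ev = inf[gi]
            hi = (ev.offset_ms if ev.modality == "vocal" else ev.onset_ms) + w_ms
            candidates = []
            for mi, mev in enumerate(mot):
                if mev.onset_ms == ev.onset_ms:
                    continue
                if mev.onset_ms < ev.onset_ms:
                    continue
                if mev.onset_ms > hi:
                    continue
                if not inclusive_end and mev.onset_ms == hi:
                    continue
                if not reuse_maternal and mi in consumed:
                    continue
                candidates.append(mi)
            if candidates:
                first = min(candidates, key=lambda mi: (mot[mi].onset_ms, mi))
                pairs.append((gi, first))
                group_hits.append(first)
        consumed.update(group_hits)
        k = max(group) + 1
    return sorted(pairs)


def kappa_from_counts(matrix: np.ndarray) -> float:
    """Cohen's kappa from a square count matrix (closed form)."""
    m = np.asarray(matrix, float)
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = (m.sum(1) @ m.sum(0)) / n**2
    return (p_o - p_e) / (1 - p_e)


def exhaustive_alignments(a_events, b_events, may_align):
    """All maximal-score monotone matchings between two event lists.

    ``may_align(ea, eb)`` gates pairs; score is 2 per same-code pair, 1 per
    different-code pair.  Returns (best_score, list_of_matchings) where a
    matching is a list of (i, j) pairs.  Feasible for n <= 8.
    """
    na, nb = len(a_events), len(b_events)
    best = [-1.0, []]

    def rec(i, j, pairs, score):
        if i == na or j == nb:
            if score > best[0]:
                best[0], best[1] = score, [list(pairs)]
            elif score == best[0]:
                best[1].append(list(pairs))
            return
        rec(i + 1, j, pairs, score)  # skip a_i
        rec(i, j + 1, pairs, score)  # skip b_j
        if may_align(a_events[i], b_events[j]):
            s = 2.0 if a_events[i][0] == b_events[j][0] else 1.0
            pairs.append((i, j))
            rec(i + 1, j + 1, pairs, score + s)
            pairs.pop()

    rec(0, 0, [], 0.0)
    # de-duplicate matchings reached via different skip orders
    uniq = {tuple(m) for m in best[1]}
    return best[0], [list(m) for m in uniq]


def alignment_kappa_for_matching(a_events, b_events, matching):
    """Kappa + percent agreement for one explicit matching (nil-padded)."""
    codes = sorted({e[0] for e in a_events} | {e[0] for e in b_events} | {"<nil>"})
    idx = {c: i for i, c in enumerate(codes)}
    m = np.zeros((len(codes), len(codes)))
    ma = {i for i, _ in matching}
    mb = {j for _, j in matching}
    agree = 0
    for i, j in matching:
        m[idx[a_events[i][0]], idx[b_events[j][0]]] += 1
        agree += a_events[i][0] == b_events[j][0]
    for i in range(len(a_events)):
        if i not in ma:
            m[idx[a_events[i][0]], idx["<nil>"]] += 1
    for j in range(len(b_events)):
        if j not in mb:
            m[idx["<nil>"], idx[b_events[j][0]]] += 1
    return kappa_from_counts(m), 100.0 * agree / m.sum()


def icc_31_mean_squares(scores: np.ndarray) -> float:
    """ICC(3,1) consistency from the two-way ANOVA mean squares."""
    x = np.asarray(scores, float)
    k, n = x.shape
    grand = x.mean()
    ms_targets = k * ((x.mean(0) - grand) ** 2).sum() / (n - 1)
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - k * ((x.mean(0) - grand) ** 2).sum() - n * ((x.mean(1) - grand) ** 2).sum()
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_targets - ms_err) / (ms_targets + (k - 1) * ms_err)


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """OLS betas and standard errors via the normal equations."""
    x = np.column_stack([np.ones(len(x)), x])
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = resid @ resid / (len(y) - x.shape[1])
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se


def responsiveness_closed_form(c, i, m, d_ms, w_ms=1000):
    return c / i - (1.0 - math.exp(-m * w_ms / d_ms))
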