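"""Group-level statistics on ROI epochs.

The post-stimulus window is divided into six 3-s time bins and averaged per
ROI and condition; a two-way repeated-measures ANOVA (condition × time bin,
both within-subject) tests for activation changes over time and condition
differences, with per-bin paired t-tests as post-hoc probes.  Per-subject
condition difference scores (contingent minus noncontingent mean HbO over
the whole window; negative = more activation to the noncontingent
condition) feed an ordinary least-squares regression on five maternal/
infant predictors: overall touch proportion, affective-touch proportion,
maternal sensitivity, the contingency responsiveness index, and infant age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .types import CONDITIONS, EpochSet

__all__ = [
    "bin_epochs",
    "assemble_bin_array",
    "rm_anova",
    "posthoc_bins",
    "diff_scores",
    "fit_regression",
    "posthoc_condition_regressions",
    "PREDICTORS",
]

PREDICTORS = ["all_touch", "affective_touch", "sensitivity", "contingency", "age_days"]


def bin_epochs(
    epochs: EpochSet, n_bins: int = 6, bin_s: float = 3.0, chromophore: str = "hbo"
) -> pd.DataFrame:
    """Per-bin time averages of the condition-averaged epochs of one subject.

    Returns a long table (roi, condition, bin, mean) with bins numbered
    1..n_bins partitioning the post-stimulus window.
    """
    fs = 1.0 / (epochs.times[1] - epochs.times[0])
    samples_per_bin = int(round(bin_s * fs))
    needed = n_bins * samples_per_bin
    if len(epochs.times) < needed:
        raise ValueError(
            f"epoch length {len(epochs.times)} samples < {needed} required for "
            f"{n_bins} bins of {bin_s} s; shorten bins or lengthen the epoch window"
        )
    rows = []
    for (roi, cond), _ in epochs.epochs.items():
        avg = epochs.condition_average(roi, cond, chromophore)
        for b in range(n_bins):
            seg = avg[b * samples_per_bin:(b + 1) * samples_per_bin]
            rows.append((roi, cond, b + 1, float(seg.mean())))
    return pd.DataFrame(rows, columns=["roi", "condition", "bin", "mean"])


def assemble_bin_array(tables: dict[int | str, pd.DataFrame], roi: str) -> np.ndarray:
    """Stack per-subject bin tables into an (n_subjects, 2, n_bins) array.

    Subjects missing the requested ROI (or either condition) are dropped.
    """
    mats = []
    for _, tab in sorted(tables.items(), key=lambda kv: str(kv[0])):
        sub = tab[tab["roi"] == roi]
        if sub.empty or set(sub["condition"]) != set(CONDITIONS):
            continue
        piv = sub.pivot(index="condition", columns="bin", values="mean")
        mats.append(piv.loc[list(CONDITIONS)].to_numpy())
    if not mats:
        raise ValueError(f"no complete subjects for ROI {roi!r}")
    return np.stack(mats)


def _gg_epsilon(y: np.ndarray) -> float:
    """Box/Greenhouse-Geisser sphericity epsilon for an (n, k) within-factor
    matrix."""
    k = y.shape[1]
    if k < 3:
        return 1.0
    s = np.cov(y, rowvar=False)
    row = s.mean(axis=0)
    d = s - row[None, :] - row[:, None] + s.mean()
    eps = np.trace(d) ** 2 / ((k - 1) * (d * d).sum())
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(data: np.ndarray, correction: str | None = None) -> dict[str, dict[str, float]]:
    """Two-way within-subject ANOVA on an (n, n_cond, n_bins) array.

    Classical sums-of-squares decomposition with subject as the random
    factor; each effect is tested against its interaction with subject.
    Degrees of freedom are uncorrected by default;
    ``correction="greenhouse-geisser"`` scales the df (and p) of the bin
    and interaction effects by the sphericity epsilon (the bin factor's
    epsilon from the condition-averaged data, the interaction's from the
    per-bin condition differences).  Returns per-effect dicts with F, df1,
    df2 and p for "condition", "bin" and "condition*bin".
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (n_subjects, n_conditions, n_bins)")
    n, a, b = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    gm = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_c = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sc = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_cb = data.mean(axis=0)

    ss_c = n * b * ((m_c - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_cb = n * ((m_cb - m_c[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_sc = b * ((m_sc - m_s[:, None] - m_c[None, :] + gm) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    resid = (
        data
        - m_sc[:, :, None]
        - m_sb[:, None, :]
        - m_cb[None, :, :]
        + m_s[:, None, None]
        + m_c[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_scb = (resid ** 2).sum()

    total_ss = ((data - gm) ** 2).sum()

    def effect(ss_eff, df_eff, ss_err, df_err):
        # an effect that is exactly absent leaves 0/0 up to float noise
        tiny = 1e-12 * max(total_ss, 1.0)
        if ss_eff <= tiny:
            return {"F": 0.0, "df1": df_eff, "df2": df_err, "p": 1.0,
                    "SS": float(ss_eff), "SS_error": float(ss_err)}
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(sp_stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        return {"F": float(f), "df1": df_eff, "df2": df_err, "p": p,
                "SS": float(ss_eff), "SS_error": float(ss_err)}

    out = {
        "condition": effect(ss_c, a - 1, ss_sc, (a - 1) * (n - 1)),
        "bin": effect(ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        "condition*bin": effect(ss_cb, (a - 1) * (b - 1), ss_scb, (a - 1) * (b - 1) * (n - 1)),
    }
    if correction in ("gg", "greenhouse-geisser"):
        for name, y in (("bin", data.mean(axis=1)), ("condition*bin", data[:, 0] - data[:, 1])):
            eps = _gg_epsilon(y)
            e = out[name]
            e["eps"] = eps
            if e["F"] > 0 and np.isfinite(e["F"]):
                e["p"] = float(sp_stats.f.sf(e["F"], eps * e["df1"], eps * e["df2"]))
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def posthoc_bins(data: np.ndarray, correction: str | None = None) -> pd.DataFrame:
    """Paired t-test per time bin, first condition vs second.

    p-values are uncorrected by default; ``correction="holm"`` applies the
    Holm step-down adjustment across bins.  Bins with zero difference
    variance are flagged as degenerate (t/p NaN).
    """
    data = np.asarray(data, dtype=float)
    n, a, b = data.shape
    if a != 2:
        raise ValueError("post-hoc bin tests need exactly two conditions")
    rows = []
    for k in range(b):
        x, y = data[:, 0, k], data[:, 1, k]
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                rows.append((k + 1, 0.0, n - 1, 1.0, float(diff.mean()), False))
            else:
                rows.append((k + 1, np.nan, n - 1, np.nan, float(diff.mean()), True))
            continue
        t, p = sp_stats.ttest_rel(x, y)
        rows.append((k + 1, float(t), n - 1, float(p), float(diff.mean()), False))
    tab = pd.DataFrame(rows, columns=["bin", "t", "df", "p", "mean_diff", "degenerate"])
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        ok = tab["p"].notna()
        adj = tab["p"].copy()
        if ok.any():
            adj.loc[ok] = multipletests(tab.loc[ok, "p"], method="holm")[1]
        tab["p_holm"] = adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return tab


def diff_scores(epochs: EpochSet, window_s: float | None = None) -> dict[str, float]:
    """Contingent-minus-noncontingent mean HbO per ROI (µM).

    Averages the condition-averaged epoch over the post-stimulus window
    (optionally truncated to ``window_s``) and subtracts the noncontingent
    from the contingent mean.  ROIs missing either condition are omitted.
    """
    out: dict[str, float] = {}
    if window_s is not None:
        n_keep = int(round(window_s / (epochs.times[1] - epochs.times[0])))
    else:
        n_keep = len(epochs.times)
    for roi in epochs.available_rois():
        try:
            cont = epochs.condition_average(roi, "contingent")[:n_keep]
            noncont = epochs.condition_average(roi, "noncontingent")[:n_keep]
        except KeyError:
            continue
        out[roi] = float(cont.mean() - noncont.mean())
    return out


@dataclass
class RegressionResult:
    table: pd.DataFrame  # index: Intercept + predictors; columns: Estimate, SE, CI low/high, t, p
    f_stat: float
    f_p: float
    adj_r2: float
    n: int


def _design(rows: pd.DataFrame, outcome: str, predictors: list[str]) -> pd.DataFrame:
    cols = predictors + [outcome]
    df = rows[cols].dropna()
    return df


def fit_regression(
    rows: pd.DataFrame,
    outcome: str,
    predictors: list[str] | None = None,
    min_n: int = 10,
) -> RegressionResult:
    """OLS of a per-dyad outcome on the five maternal/infant predictors.

    ``rows`` has one row per dyad with predictor columns and the outcome
    column; rows with any missing value are dropped (listwise deletion).
    """
    import statsmodels.api as sm

    predictors = predictors or PREDICTORS
    df = _design(rows, outcome, predictors)
    if len(df) < min_n:
        raise ValueError(f"only {len(df)} complete rows; need at least {min_n}")
    x = sm.add_constant(df[predictors], has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        sub = df[predictors]
        corr = sub.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear predictors: {worst}")
    fit = sm.OLS(df[outcome], x).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "Estimate": fit.params,
            "SE": fit.bse,
            "CI_low": ci[0],
            "CI_high": ci[1],
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    table.index = ["Intercept"] + predictors
    return RegressionResult(
        table=table,
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        adj_r2=float(fit.rsquared_adj),
        n=len(df),
    )


def posthoc_condition_regressions(
    rows: pd.DataFrame,
    contingent_col: str = "act_contingent",
    noncontingent_col: str = "act_noncontingent",
    predictors: list[str] | None = None,
    min_n: int = 10,
) -> dict[str, RegressionResult]:
    """The same OLS applied to each condition's mean activation separately."""
    return {
        "contingent": fit_regression(rows, contingent_col, predictors, min_n),
        "noncontingent": fit_regression(rows, noncontingent_col, predictors, min_n),
    }
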