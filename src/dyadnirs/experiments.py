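"""End-to-end simulation experiments with known ground truth.

These functions wire the generators, the behavioral scoring, the fNIRS
pipeline and the group statistics together for calibration and recovery
studies: a cohort in which maternal sensitivity and overall touch attenuate
the noncontingent-condition response, so that the difference-score
regression should recover positive coefficients for both predictors on a
negative-mean difference score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contingency import contingency_pipeline
from .preproc import PreprocConfig, preprocess
from .stats import diff_scores
from .synthetic import (
    DyadSimConfig,
    MotionConfig,
    NirsSimConfig,
    NoiseConfig,
    roi_montage,
    simulate_dyad,
    simulate_nirs,
    simulate_touch,
)
from .types import UndefinedIndexError

__all__ = ["simulate_recovery_cohort", "cohort_regression_frame"]


def _touch_probs(p_touch: float, p_affective: float, rng: np.random.Generator) -> dict:
    """Category probabilities with a controlled total-touch and affective share."""
    others = ["playful", "attention_getting", "instrumental", "static", "incidental", "harsh"]
    w = rng.dirichlet(np.ones(len(others)))
    rest = max(p_touch - p_affective, 0.0)
    probs = {"affective": min(p_affective, p_touch), "none": 1.0 - p_touch}
    probs.update({c: rest * wi for c, wi in zip(others, w)})
    return probs


def simulate_recovery_cohort(
    n_subjects: int = 200,
    seed: int = 0,
    amp_contingent: float = 0.2,
    base_noncontingent: float = 0.5,
    gamma_sensitivity: float = 0.10,
    gamma_touch: float = 0.004,
    n_trials_per_condition: int = 6,
    preproc_cfg: PreprocConfig | None = None,
) -> pd.DataFrame:
    """Simulate a cohort where sensitivity and touch attenuate the
    noncontingent right-ROI response.

    Per dyad the right-ROI noncontingent HbO amplitude (µM) is
    ``base − γ_s·(sensitivity − 5) − γ_t·(all_touch% − 62)`` while the
    contingent amplitude is constant; behavioral covariates come from the
    behavioral generators scored by the real pipelines.  Returns one row
    per included dyad with predictors, difference scores and per-condition
    mean activations.
    """
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=(n_subjects, 3))
    preproc_cfg = preproc_cfg or PreprocConfig()
    montage = roi_montage()

    rows = []
    for i in range(n_subjects):
        rng = np.random.default_rng(sub_seeds[i, 0])
        sensitivity = float(np.clip(rng.normal(5.08, 1.11), 1, 7))
        age_days = float(rng.normal(152, 10))

        p_touch = float(np.clip(rng.normal(0.62, 0.27), 0.02, 0.98))
        p_aff = float(np.clip(rng.normal(0.10, 0.09), 0.0, p_touch))
        touch = simulate_touch(int(sub_seeds[i, 1]), 150, _touch_probs(p_touch, p_aff, rng))
        from .touch import aggregate_touch

        props = aggregate_touch(touch)
        all_touch_pct = 100.0 * props["all_touch"]
        affective_pct = 100.0 * props["affective"]

        dyad_cfg = DyadSimConfig(
            response_prob=float(rng.uniform(0.15, 0.85)),
            duration_ms=300_000,
            seed=int(sub_seeds[i, 1]) ^ 0x5A5A,
        )
        mother, infant, gaze = simulate_dyad(dyad_cfg)
        try:
            contingency = contingency_pipeline(mother, infant, gaze).index
        except UndefinedIndexError:
            contingency = np.nan

        amp_nc = (
            base_noncontingent
            - gamma_sensitivity * (sensitivity - 5.08)
            - gamma_touch * (all_touch_pct - 62.0)
        )
        nirs_cfg = NirsSimConfig(
            n_trials_per_condition=n_trials_per_condition,
            hrf_amplitude={
                ("contingent", "right"): amp_contingent,
                ("noncontingent", "right"): amp_nc,
                ("contingent", "left"): 0.41,
                ("noncontingent", "left"): 0.50,
            },
            noise=NoiseConfig(white_sd_um=0.05, drift_amp_um=0.1),
            motion=MotionConfig.none(),
            looking_dist=(6.0, 1.0),
            seed=int(sub_seeds[i, 2]),
        )
        rec = simulate_nirs(nirs_cfg, montage)
        epochs, _ = preprocess(rec, preproc_cfg)
        if epochs is None:
            continue
        d = diff_scores(epochs)
        row = {
            "subject": i,
            "sensitivity": sensitivity,
            "all_touch": all_touch_pct,
            "affective_touch": affective_pct,
            "contingency": contingency,
            "age_days": age_days,
            "diff_right": d.get("right", np.nan),
            "diff_left": d.get("left", np.nan),
            "true_amp_noncontingent": amp_nc,
        }
        for cond in ("contingent", "noncontingent"):
            try:
                row[f"act_{cond}"] = float(epochs.condition_average("right", cond).mean())
            except KeyError:
                row[f"act_{cond}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_regression_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows ready for :func:`dyadnirs.stats.fit_regression` (listwise-complete)."""
    cols = ["all_touch", "affective_touch", "sensitivity", "contingency", "age_days",
            "diff_right", "diff_left", "act_contingent", "act_noncontingent"]
    return cohort[cols].dropna(subset=["diff_right"])
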