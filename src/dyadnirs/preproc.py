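"""fNIRS preprocessing: raw intensity to baseline-corrected ROI epochs.

The pipeline applies, in order: (1) trial rejection by infant looking
(> 50% of the trial and ≥ 50% of the brushing period); (2) channel pruning
by raw-intensity range (0.09–1 V) and signal-to-noise ratio (≥ 0 dB);
(3) conversion to optical density; (4) motion-artifact detection (signal
change exceeding 14 SD of the channel's sample-to-sample noise or 0.4 OD
within 1 s); (5) wavelet-based artifact correction (outlier detail
coefficients beyond 0.5 IQR of the quartiles zeroed); (6) an automated
heart-rate quality check (a cardiac spectral peak must be visible);
(7) residual-artifact detection and rejection of contaminated trials,
re-applying the minimum of three valid trials per condition; (8) zero-phase
band-pass filtering 0.01–1 Hz; (9) modified Beer-Lambert conversion to
HbO/HbR with DPF 5.1; (10) epoching and channel averaging within each ROI
(kept only with at least two surviving channels).

Every exclusion decision is a pure function of the inputs and the
configuration; :func:`preprocess` records the applied stage order and
parameters in a run manifest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, signal

from .beer_lambert import od_to_conc
from .types import CONDITIONS, ROI_CHANNELS, EpochSet, Montage, NirsRecording

__all__ = [
    "PreprocConfig",
    "filter_trials_by_looking",
    "prune_channels",
    "intensity_to_od",
    "detect_motion",
    "mask_to_segments",
    "wavelet_correct",
    "heart_rate_check",
    "reject_contaminated_trials",
    "bandpass",
    "od_to_concentration",
    "build_epochs",
    "preprocess",
]


@dataclass
class PreprocConfig:
    looking_trial_min: float = 0.5      # strict > for the trial period
    looking_brush_min: float = 0.5      # >= for the brushing period
    intensity_range_v: tuple[float, float] = (0.09, 1.0)
    snr_min_db: float = 0.0
    motion_window_s: float = 1.0
    motion_sd_thresh: float = 14.0
    motion_amp_thresh: float = 0.4
    wavelet: str = "db5"
    wavelet_iqr: float = 0.5
    wavelet_approx_hz: float = 0.12     # approximation band kept untouched
    hr_band_hz: tuple[float, float] = (1.5, 3.5)
    hr_prominence_ratio: float = 3.0
    hr_nperseg: int = 256
    bandpass_hz: tuple[float, float] = (0.01, 1.0)
    bandpass_order: int = 4
    dpf: float = 5.1
    trial_s: float = 15.0
    epoch_s: float = 18.0
    baseline_ref_s: float = 3.0
    min_trials_per_condition: int = 3
    min_roi_channels: int = 2
    reject_span: str = "baseline+trial"  # or "trial"
    enable_motion_correction: bool = True
    enable_heart_rate_check: bool = True


def filter_trials_by_looking(rec: NirsRecording, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Boolean validity per trial from the looking annotations.

    A trial is valid iff the infant looked at the screen for strictly more
    than half of the trial and for at least half of the brushing period.
    Trials with missing looking data are invalid (with a warning).
    """
    cfg = cfg or PreprocConfig()
    n_trials = len(rec.markers)
    mask = np.zeros(n_trials, dtype=bool)
    look = rec.looking.set_index("trial")
    for trial in rec.markers["trial"]:
        if trial not in look.index:
            warnings.warn(f"trial {trial}: no looking data, marked invalid")
            continue
        row = look.loc[trial]
        ft, fb = row["frac_trial_looking"], row["frac_brush_looking"]
        if np.isnan(ft) or np.isnan(fb):
            warnings.warn(f"trial {trial}: missing looking fraction, marked invalid")
            continue
        mask[trial] = (ft > cfg.looking_trial_min) and (fb >= cfg.looking_brush_min)
    return mask


def meets_min_trials(
    trial_mask: np.ndarray, markers: pd.DataFrame, min_trials: int = 3
) -> bool:
    """Subject inclusion: at least ``min_trials`` valid trials per condition."""
    for cond in CONDITIONS:
        in_cond = (markers["condition"] == cond).to_numpy()
        if int(trial_mask[in_cond].sum()) < min_trials:
            return False
    return True


def prune_channels(rec: NirsRecording, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Boolean keep-mask per channel from raw-intensity range and SNR.

    A channel is dropped when, at either wavelength, its mean intensity
    falls outside the accepted range or 20·log10(mean/SD) is below the SNR
    floor.
    """
    cfg = cfg or PreprocConfig()
    lo, hi = cfg.intensity_range_v
    mean = rec.intensity.mean(axis=2)  # (n_ch, 2)
    sd = rec.intensity.std(axis=2, ddof=0)
    in_range = (mean >= lo) & (mean <= hi)
    with np.errstate(divide="ignore"):
        snr_db = 20.0 * np.log10(np.where(sd > 0, mean / sd, np.inf))
    return (in_range & (snr_db >= cfg.snr_min_db)).all(axis=1)


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """OD(t) = −ln(I(t) / mean(I)) along the last axis."""
    if (intensity <= 0).any():
        bad = np.argwhere((intensity <= 0).any(axis=-1))
        raise ValueError(f"non-positive intensity samples in channel/wavelength {bad[0].tolist()}")
    mean = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / mean)


def detect_motion(
    od: np.ndarray, fs: float, cfg: PreprocConfig | None = None
) -> np.ndarray:
    """Per-channel boolean artifact mask over time.

    A sample is flagged when the signal range within the 1-s window centred
    on it exceeds the absolute OD threshold or ``sd_thresh`` times the
    channel's first-difference standard deviation (a sample-to-sample noise
    estimate), at either wavelength; flagged windows are then expanded so
    the whole offending window is marked.
    """
    cfg = cfg or PreprocConfig()
    win = max(3, int(round(cfg.motion_window_s * fs)))
    rng_map = ndimage.maximum_filter1d(od, size=win, axis=-1) - ndimage.minimum_filter1d(
        od, size=win, axis=-1
    )
    sd_diff = np.diff(od, axis=-1).std(axis=-1, ddof=0)  # (n_ch, 2)
    thresh = np.minimum(cfg.motion_amp_thresh, cfg.motion_sd_thresh * sd_diff)
    flagged = rng_map > thresh[..., None]
    flagged = ndimage.binary_dilation(flagged, structure=np.ones((1, 1, win), bool))
    return flagged.any(axis=1)  # (n_ch, n_t)


def mask_to_segments(mask_row: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean vector as (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_row.view(np.int8), [0]))))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def _wavelet_level(fs: float, approx_hz: float, n_t: int, wavelet: str) -> int:
    level = max(1, int(math.floor(math.log2(fs / (2.0 * approx_hz)))))
    return min(level, pywt.dwt_max_level(n_t, pywt.Wavelet(wavelet)))


def wavelet_correct(
    od: np.ndarray,
    artifact_mask: np.ndarray,
    fs: float,
    cfg: PreprocConfig | None = None,
) -> np.ndarray:
    """Suppress motion artifacts by zeroing outlier wavelet detail coefficients.

    Channels without any flagged sample pass through unchanged.  For flagged
    channels the signal is decomposed (Daubechies family) down to a detail
    scale of about ``wavelet_approx_hz``; detail coefficients lying more
    than ``wavelet_iqr``·IQR beyond the quartiles at their level are set to
    zero and the signal is reconstructed.  The hemodynamic band lives in
    the untouched approximation, so clean signals are nearly unaffected.
    """
    cfg = cfg or PreprocConfig()
    n_ch, _, n_t = od.shape
    if n_t < 16:
        raise ValueError("signal too short for wavelet decomposition")
    out = od.copy()
    target = np.flatnonzero(artifact_mask.any(axis=-1))
    if target.size == 0:
        return out
    level = _wavelet_level(fs, cfg.wavelet_approx_hz, n_t, cfg.wavelet)
    flat = od[target].reshape(-1, n_t)  # (n_sig, n_t)
    coeffs = pywt.wavedec(flat, cfg.wavelet, level=level, axis=-1)
    for d in coeffs[1:]:
        q1, q3 = np.quantile(d, [0.25, 0.75], axis=-1, keepdims=True)
        iqr = q3 - q1
        outlier = (d < q1 - cfg.wavelet_iqr * iqr) | (d > q3 + cfg.wavelet_iqr * iqr)
        d[outlier] = 0.0
    rec = pywt.waverec(coeffs, cfg.wavelet, axis=-1)[..., :n_t]
    out[target] = rec.reshape(len(target), 2, n_t)
    return out


def heart_rate_check(
    od: np.ndarray, fs: float, cfg: PreprocConfig | None = None
) -> np.ndarray:
    """Boolean pass-mask per channel: a cardiac spectral peak is visible.

    Automated surrogate for visual inspection: the Welch spectrum must show
    a peak in the cardiac band whose height exceeds
    ``hr_prominence_ratio`` times the median in-band power, at both
    wavelengths.
    """
    cfg = cfg or PreprocConfig()
    lo, hi = cfg.hr_band_hz
    if fs <= 2 * lo:
        raise ValueError("sampling rate too low to resolve the cardiac band")
    nperseg = min(cfg.hr_nperseg, od.shape[-1])
    freqs, psd = signal.welch(od, fs=fs, nperseg=nperseg, axis=-1)
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 3:
        raise ValueError("cardiac band unresolved at this sampling rate")
    in_band = psd[..., band]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = in_band.max(axis=-1) / np.median(in_band, axis=-1)
    passed = np.where(np.isfinite(ratio), ratio, 0.0) >= cfg.hr_prominence_ratio
    return passed.all(axis=1)  # both wavelengths


def reject_contaminated_trials(
    artifact_mask: np.ndarray,
    markers: pd.DataFrame,
    fs: float,
    channel_idx: np.ndarray | None = None,
    cfg: PreprocConfig | None = None,
) -> np.ndarray:
    """Boolean keep-mask per trial: no residual artifact in the trial span.

    The contamination span is the baseline plus trial period by default
    (``reject_span="trial"`` restricts it to the trial itself), evaluated
    over ``channel_idx`` (defaults to all channels in the mask).
    """
    cfg = cfg or PreprocConfig()
    if channel_idx is None:
        channel_idx = np.arange(artifact_mask.shape[0])
    combined = (
        artifact_mask[channel_idx].any(axis=0)
        if len(channel_idx)
        else np.zeros(artifact_mask.shape[-1], bool)
    )
    n_t = artifact_mask.shape[-1]
    keep = np.ones(len(markers), dtype=bool)
    for k, row in markers.iterrows():
        start_s = row["baseline_onset_s"] if cfg.reject_span == "baseline+trial" else row["onset_s"]
        i0 = max(0, int(round(start_s * fs)))
        i1 = min(n_t, int(round((row["onset_s"] + cfg.trial_s) * fs)))
        if combined[i0:i1].any():
            keep[int(row["trial"])] = False
    return keep


def bandpass(
    x: np.ndarray, fs: float, low: float = 0.01, high: float = 1.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis (DC removed)."""
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for a {high} Hz band edge")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def od_to_concentration(
    od: np.ndarray, montage: Montage, dpf: float = 5.1,
    wavelengths: tuple[float, float] = (760.0, 850.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel modified Beer-Lambert inversion; returns (HbO, HbR) µM."""
    n_ch = od.shape[0]
    hbo = np.empty((n_ch, od.shape[-1]))
    hbr = np.empty_like(hbo)
    for ci in range(n_ch):
        d_mm = float(montage.table["distance_mm"].iloc[ci])
        hbo[ci], hbr[ci] = od_to_conc(od[ci], d_mm, dpf, wavelengths)
    return hbo, hbr


def build_epochs(
    hbo: np.ndarray,
    hbr: np.ndarray,
    fs: float,
    markers: pd.DataFrame,
    trial_mask: np.ndarray,
    channel_mask: np.ndarray,
    montage: Montage,
    cfg: PreprocConfig | None = None,
) -> tuple[EpochSet | None, dict]:
    """Cut baseline-corrected condition epochs and average channels per ROI.

    Each epoch spans ``epoch_s`` from trial onset and is corrected by the
    mean of the final ``baseline_ref_s`` of the preceding baseline.  An ROI
    is kept only when at least ``min_roi_channels`` of its channels
    survived; the subject is included only when both conditions retain at
    least ``min_trials_per_condition`` valid trials.
    """
    cfg = cfg or PreprocConfig()
    n_t = hbo.shape[-1]
    n_ep = int(round(cfg.epoch_s * fs))
    n_ref = int(round(cfg.baseline_ref_s * fs))
    channels = montage.channels

    report: dict = {"roi_channels": {}, "valid_trials": {}}
    epochs: dict = {}
    times = np.arange(n_ep) / fs

    # drop trials whose epoch would run off the end of the recording
    trial_mask = trial_mask.copy()
    for k, row in markers.iterrows():
        i_on = int(round(row["onset_s"] * fs))
        if i_on + n_ep > n_t or i_on - n_ref < 0:
            trial_mask[int(row["trial"])] = False

    included = meets_min_trials(trial_mask, markers, cfg.min_trials_per_condition)
    for cond in CONDITIONS:
        in_cond = (markers["condition"] == cond).to_numpy()
        report["valid_trials"][cond] = int(trial_mask[in_cond].sum())
    if not included:
        report["excluded_reason"] = "fewer than minimum valid trials in a condition"
        return None, report

    for roi, roi_chs in ROI_CHANNELS.items():
        idx = [i for i, ch in enumerate(channels) if ch in roi_chs and channel_mask[i]]
        report["roi_channels"][roi] = [int(channels[i]) for i in idx]
        if len(idx) < cfg.min_roi_channels:
            continue
        roi_hbo = hbo[idx].mean(axis=0)
        roi_hbr = hbr[idx].mean(axis=0)
        for cond in CONDITIONS:
            rows = markers[(markers["condition"] == cond)]
            ep_o, ep_r = [], []
            for _, row in rows.iterrows():
                if not trial_mask[int(row["trial"])]:
                    continue
                i_on = int(round(row["onset_s"] * fs))
                base_o = roi_hbo[i_on - n_ref:i_on].mean()
                base_r = roi_hbr[i_on - n_ref:i_on].mean()
                ep_o.append(roi_hbo[i_on:i_on + n_ep] - base_o)
                ep_r.append(roi_hbr[i_on:i_on + n_ep] - base_r)
            epochs[(roi, cond)] = {"hbo": np.array(ep_o), "hbr": np.array(ep_r)}

    if not epochs:
        report["excluded_reason"] = "no ROI with enough surviving channels"
        return None, report
    eset = EpochSet(
        epochs=epochs,
        times=times,
        valid_trial_counts=report["valid_trials"],
        rois=tuple(sorted({roi for roi, _ in epochs})),
    )
    return eset, report


def preprocess(
    rec: NirsRecording, cfg: PreprocConfig | None = None
) -> tuple[EpochSet | None, dict]:
    """Run the full preprocessing chain on one recording.

    Returns the subject's epoch set (or None when excluded) and a manifest
    dict recording the stage order, parameters and every exclusion
    decision.
    """
    cfg = cfg or PreprocConfig()
    manifest: dict = {
        "stage_order": [
            "looking_filter", "channel_prune", "optical_density",
            "motion_detect", "wavelet_correct", "heart_rate_check",
            "residual_motion_trial_reject", "bandpass", "beer_lambert",
            "roi_epochs",
        ],
        "parameters": asdict(cfg),
    }

    looking_mask = filter_trials_by_looking(rec, cfg)
    manifest["looking_valid"] = looking_mask.tolist()

    keep_ch = prune_channels(rec, cfg)
    manifest["pruned_channels"] = [int(c) for c in rec.montage.channels[~keep_ch]]

    od = intensity_to_od(rec.intensity)

    artifact = detect_motion(od, rec.fs, cfg)
    manifest["artifact_samples_per_channel"] = artifact.sum(axis=-1).tolist()

    if cfg.enable_motion_correction:
        od = wavelet_correct(od, artifact, rec.fs, cfg)

    if cfg.enable_heart_rate_check:
        hr_ok = heart_rate_check(od, rec.fs, cfg)
    else:
        hr_ok = np.ones(rec.n_channels, bool)
    manifest["heart_rate_failed"] = [int(c) for c in rec.montage.channels[~hr_ok]]
    keep_ch = keep_ch & hr_ok

    if cfg.enable_motion_correction:
        residual = detect_motion(od, rec.fs, cfg)
        roi_all = set(ROI_CHANNELS["left"]) | set(ROI_CHANNELS["right"])
        roi_idx = np.array(
            [i for i, ch in enumerate(rec.montage.channels) if ch in roi_all and keep_ch[i]],
            dtype=int,
        )
        motion_keep = reject_contaminated_trials(residual, rec.markers, rec.fs, roi_idx, cfg)
    else:
        motion_keep = np.ones(len(rec.markers), bool)
    manifest["motion_rejected_trials"] = [int(t) for t in rec.markers["trial"][~motion_keep]]
    trial_mask = looking_mask & motion_keep

    lo, hi = cfg.bandpass_hz
    od = bandpass(od, rec.fs, lo, hi, cfg.bandpass_order)

    hbo, hbr = od_to_concentration(od, rec.montage, cfg.dpf, rec.wavelengths)

    eset, epoch_report = build_epochs(
        hbo, hbr, rec.fs, rec.markers, trial_mask, keep_ch, rec.montage, cfg
    )
    manifest.update(epoch_report)
    manifest["included"] = eset is not None
    return eset, manifest
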