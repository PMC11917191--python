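"""Block-design infant fNIRS generator with a known forward model.

Ground-truth HbO responses are condition-specific double-gamma hemodynamic
response functions convolved with 15-s trial boxcars (each trial preceded
by a 12-s baseline; conditions tile an ABBABAAB order starting with the
contingent condition).  HbR mirrors HbO with a negative scaling.
Physiological noise (cardiac ~2.5 Hz for an infant heart rate around
150 bpm, respiration ~0.6 Hz, Mayer waves ~0.1 Hz), slow drift and white
noise are added in concentration space; the result is forward-projected to
760/850 nm intensity through the same modified Beer-Lambert model the
preprocessing pipeline inverts.  Motion spikes are injected in optical
density.  The generator stores its ground truth on the recording so
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from ..beer_lambert import conc_to_od
from ..types import CONDITIONS, ROI_CHANNELS, Montage, NirsRecording

__all__ = [
    "HrfParams",
    "NoiseConfig",
    "MotionConfig",
    "NirsSimConfig",
    "double_gamma_hrf",
    "condition_order",
    "default_montage",
    "roi_montage",
    "simulate_nirs",
]

CONDITION_PATTERN = "ABBABAAB"  # A = contingent


@dataclass
class HrfParams:
    """Double-gamma HRF shape; peak of the positive lobe normalised to 1."""

    peak_s: float = 5.0
    undershoot_s: float = 15.0
    undershoot_ratio: float = 0.35
    dispersion: float = 1.0
    length_s: float = 30.0


@dataclass
class NoiseConfig:
    """Physiological + instrumental noise amplitudes (µM) and frequencies (Hz)."""

    cardiac_hz: float = 2.5
    cardiac_amp_um: float = 0.15
    resp_hz: float = 0.6
    resp_amp_um: float = 0.10
    mayer_hz: float = 0.1
    mayer_amp_um: float = 0.10
    drift_amp_um: float = 0.20
    white_sd_um: float = 0.05
    hbr_scale: float = 0.3  # physiological noise is weaker on HbR

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(cardiac_amp_um=0, resp_amp_um=0, mayer_amp_um=0,
                   drift_amp_um=0, white_sd_um=0)


@dataclass
class MotionConfig:
    """Motion-spike injection in OD units."""

    spikes_per_minute: float = 0.0  # per channel
    amp_od: tuple[float, float] = (0.45, 1.2)
    decay_s: float = 0.2

    @classmethod
    def none(cls) -> "MotionConfig":
        return cls(spikes_per_minute=0.0)


@dataclass
class NirsSimConfig:
    """Design and signal parameters of one simulated fNIRS session."""

    n_trials_per_condition: int = 10
    baseline_s: float = 12.0
    trial_s: float = 15.0
    tail_s: float = 12.0
    sampling_hz: float = 7.8125
    #: µM HbO block-response amplitude per (condition, roi)
    hrf_amplitude: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("contingent", "left"): 0.41,
            ("noncontingent", "left"): 0.50,
            ("contingent", "right"): 0.35,
            ("noncontingent", "right"): 0.50,
        }
    )
    hbr_ratio: float = -0.35
    hrf: HrfParams = field(default_factory=HrfParams)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    #: Beta(a, b) for per-trial looking fractions (screen and brush period)
    looking_dist: tuple[float, float] = (3.5, 1.5)
    dpf: float = 5.1
    wavelengths: tuple[float, float] = (760.0, 850.0)
    mean_intensity_v: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1 or self.n_trials_per_condition > 10:
            raise ValueError("n_trials_per_condition must be in 1..10")
        if not all(np.isfinite(list(self.hrf_amplitude.values()))):
            raise ValueError("hrf_amplitude values must be finite")
        if self.sampling_hz <= 2 * self.noise.cardiac_hz:
            raise ValueError("sampling rate must exceed twice the cardiac frequency")


def double_gamma_hrf(fs: float, params: HrfParams | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``fs``, positive peak = 1."""
    p = params or HrfParams()
    t = np.arange(0, p.length_s, 1.0 / fs)
    peak = gamma_dist.pdf(t, p.peak_s / p.dispersion, scale=p.dispersion)
    under = gamma_dist.pdf(t, p.undershoot_s / p.dispersion, scale=p.dispersion)
    h = peak - p.undershoot_ratio * under
    return h / h.max()


def condition_order(n_trials: int) -> list[str]:
    """First ``n_trials`` of the tiled ABBABAAB pattern (A = contingent)."""
    reps = -(-n_trials // len(CONDITION_PATTERN))
    letters = (CONDITION_PATTERN * reps)[:n_trials]
    return [CONDITIONS[0] if c == "A" else CONDITIONS[1] for c in letters]


def _montage_frame(channels: np.ndarray) -> Montage:
    n = len(channels)
    return Montage(
        pd.DataFrame(
            {
                "channel": channels,
                "source": 1 + (channels - 1) // 4,
                "detector": 1 + (channels - 1) % 16,
                "distance_mm": 20.0 + 5.0 * ((channels - 1) % 6) / 5.0,
                "hemisphere": np.where(channels <= 15, "right", "left"),
            }
        )
    )


def default_montage() -> Montage:
    """Full 30-channel bilateral temporal montage (8 sources, 16 detectors)."""
    return _montage_frame(np.arange(1, 31))


def roi_montage() -> Montage:
    """Reduced montage containing only the 8 ROI channels (fast simulations)."""
    chans = np.array(sorted(ROI_CHANNELS["right"] + ROI_CHANNELS["left"]))
    return _montage_frame(chans)


def _physio_noise(n_t: int, fs: float, cfg: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_t) / fs
    out = np.zeros(n_t)
    for freq, amp in (
        (cfg.cardiac_hz, cfg.cardiac_amp_um),
        (cfg.resp_hz, cfg.resp_amp_um),
        (cfg.mayer_hz, cfg.mayer_amp_um),
    ):
        if amp > 0:
            f = freq * rng.uniform(0.95, 1.05)
            out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if cfg.drift_amp_um > 0:
        x = t / t[-1]
        out += cfg.drift_amp_um * (rng.normal() * x + rng.normal() * x**2)
    if cfg.white_sd_um > 0:
        out += rng.normal(0, cfg.white_sd_um, n_t)
    return out


def simulate_nirs(cfg: NirsSimConfig, montage: Montage | None = None) -> NirsRecording:
    """Simulate one session; ground truth is stored on the recording.

    ``rec.ground_truth`` holds per-channel noiseless HbO/HbR µM traces
    ("hbo_clean"/"hbr_clean"), the noisy generated concentrations
    ("hbo"/"hbr"), injected spike times per channel ("spike_times_s") and
    the condition order.
    """
    montage = montage or default_montage()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_hz
    n_trials = 2 * cfg.n_trials_per_condition
    order = condition_order(n_trials)

    block_s = cfg.baseline_s + cfg.trial_s
    total_s = n_trials * block_s + cfg.tail_s
    n_t = int(round(total_s * fs))
    t = np.arange(n_t) / fs

    trial_onsets = cfg.baseline_s + block_s * np.arange(n_trials)
    markers = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "condition": order,
            "baseline_onset_s": trial_onsets - cfg.baseline_s,
            "onset_s": trial_onsets,
        }
    )

    # ROI-level noiseless HbO: condition-amplitude boxcars convolved with the
    # HRF, scaled so a single trial's response averages to the configured
    # amplitude over the post-stimulus analysis window (trial + 3 s).
    hrf = double_gamma_hrf(fs, cfg.hrf)
    n_trial_samp = int(round(cfg.trial_s * fs))
    n_window = int(round((cfg.trial_s + 3.0) * fs))
    unit = np.convolve(np.ones(n_trial_samp), hrf)[:n_window]
    hrf = hrf / unit.mean()
    roi_clean: dict[str, np.ndarray] = {}
    for roi in ("left", "right"):
        boxcar = np.zeros(n_t)
        for onset, cond in zip(trial_onsets, order):
            amp = cfg.hrf_amplitude.get((cond, roi), 0.0)
            i0 = int(round(onset * fs))
            i1 = min(n_t, int(round((onset + cfg.trial_s) * fs)))
            boxcar[i0:i1] = amp
        roi_clean[roi] = np.convolve(boxcar, hrf)[:n_t]

    channels = montage.channels
    n_ch = len(channels)
    hbo_clean = np.zeros((n_ch, n_t))
    hbr_clean = np.zeros((n_ch, n_t))
    for ci, ch in enumerate(channels):
        for roi, roi_chs in ROI_CHANNELS.items():
            if ch in roi_chs:
                hbo_clean[ci] = roi_clean[roi]
                hbr_clean[ci] = cfg.hbr_ratio * roi_clean[roi]

    hbo = hbo_clean + np.stack([_physio_noise(n_t, fs, cfg.noise, rng) for _ in range(n_ch)])
    hbr = hbr_clean + cfg.noise.hbr_scale * np.stack(
        [_physio_noise(n_t, fs, cfg.noise, rng) for _ in range(n_ch)]
    )

    intensity = np.empty((n_ch, 2, n_t))
    spike_times: list[list[float]] = []
    i0_lo, i0_hi = cfg.mean_intensity_v
    for ci in range(n_ch):
        d_mm = float(montage.table["distance_mm"].iloc[ci])
        od = conc_to_od(hbo[ci], hbr[ci], d_mm, cfg.dpf, cfg.wavelengths)

        spikes_ci: list[dict] = []
        if cfg.motion.spikes_per_minute > 0:
            n_spikes = rng.poisson(cfg.motion.spikes_per_minute * total_s / 60.0)
            for _ in range(n_spikes):
                t0 = rng.uniform(5.0, total_s - 5.0)
                amp = rng.uniform(*cfg.motion.amp_od) * rng.choice([-1.0, 1.0])
                shape = amp * np.exp(-np.abs(t - t0) / cfg.motion.decay_s)
                contrib = [shape * rng.uniform(0.9, 1.1) for _ in range(2)]
                od[0] += contrib[0]
                od[1] += contrib[1]
                # realized amplitude: the spike's largest sampled excursion
                realized = float(max(np.abs(c).max() for c in contrib))
                spikes_ci.append({"t_s": float(t0), "amp_od": realized})
        spike_times.append(sorted(spikes_ci, key=lambda s: s["t_s"]))

        i0 = rng.uniform(i0_lo, i0_hi)
        intensity[ci] = i0 * np.exp(-od)

    a, b = cfg.looking_dist
    if b == 0:  # degenerate: infant looks for the full trial, always
        frac_trial = frac_brush = np.ones(n_trials)
    else:
        frac_trial = rng.beta(a, b, n_trials)
        frac_brush = rng.beta(a, b, n_trials)
    looking = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "frac_trial_looking": frac_trial,
            "frac_brush_looking": frac_brush,
        }
    )
    brush_intervals = [
        [(float(on + off0), float(on + off0 + 0.7)) for off0 in (2.0, 6.0, 10.0)]
        for on in trial_onsets
    ]

    ground_truth = {
        "hbo_clean": hbo_clean,
        "hbr_clean": hbr_clean,
        "hbo": hbo,
        "hbr": hbr,
        "spikes": spike_times,
        "spike_times_s": [[s["t_s"] for s in ch] for ch in spike_times],
        "condition_order": order,
        "hrf_amplitude": dict(cfg.hrf_amplitude),
    }
    return NirsRecording(
        intensity=intensity,
        fs=fs,
        montage=montage,
        markers=markers,
        looking=looking,
        wavelengths=cfg.wavelengths,
        brush_intervals=brush_intervals,
        ground_truth=ground_truth,
    )
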