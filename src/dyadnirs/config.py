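"""Run configuration: a validated, serialisable record of every stage parameter.

The configuration is strict (unknown keys are rejected) and is serialised
verbatim into the run manifest so that any run can be reproduced from its
manifest alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DyadParams(_Strict):
    duration_ms: int = 240_000
    infant_rate: float = 0.1
    maternal_base_rate: float = 0.1
    response_prob: float = 0.5
    response_latency_low_ms: float = 100.0
    response_latency_high_ms: float = 900.0
    gaze_coverage: float = 0.8


class ContingencyParams(_Strict):
    window_ms: int = 1000
    warmup_ms: int = 60_000
    coded_ms: int = 240_000
    inclusive_end: bool = True
    reuse_maternal: bool = True


class NirsParams(_Strict):
    n_trials_per_condition: int = 10
    sampling_hz: float = 7.8125
    baseline_s: float = 12.0
    trial_s: float = 15.0


class PreprocParams(_Strict):
    dpf: float = 5.1
    motion_sd_thresh: float = 14.0
    motion_amp_thresh: float = 0.4
    motion_window_s: float = 1.0
    wavelet_iqr: float = 0.5
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 1.0
    epoch_s: float = 18.0
    baseline_ref_s: float = 3.0
    min_trials_per_condition: int = 3
    min_roi_channels: int = 2
    enable_heart_rate_check: bool = True


class StatsParams(_Strict):
    n_bins: int = 6
    bin_s: float = 3.0
    min_regression_n: int = 10


class RunConfig(_Strict):
    seed: int = 0
    n_subjects: int = 12
    simulate: bool = True
    out_dir: str = "run"
    input_dir: Optional[str] = None
    run_preproc: bool = True
    run_stats: bool = True
    dyad: DyadParams = DyadParams()
    contingency: ContingencyParams = ContingencyParams()
    nirs: NirsParams = NirsParams()
    preproc: PreprocParams = PreprocParams()
    stats: StatsParams = StatsParams()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
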