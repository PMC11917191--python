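"""Readers and writers for the package's on-disk formats.

Behavioral event streams and touch codes travel as plain CSV; fNIRS
recordings as SNIRF (HDF5) or as a wide TSV dialect (one column per
channel × wavelength) with a JSON sidecar holding markers, looking
annotations and the montage.  Epoch tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import Event, EventStream, GazeEpisodes, Montage, NirsRecording, TouchRecord

__all__ = [
    "write_event_streams",
    "read_event_streams",
    "write_gaze",
    "read_gaze",
    "write_touch",
    "read_touch",
    "write_snirf",
    "read_snirf",
    "write_nirs_tsv",
    "read_nirs_tsv",
    "write_epochs_tsv",
]

EVENT_COLUMNS = ["actor", "modality", "code", "onset_ms", "offset_ms"]


def write_event_streams(path: str | Path, *streams: EventStream) -> None:
    pd.concat([s.to_frame() for s in streams], ignore_index=True).to_csv(path, index=False)


def read_event_streams(path: str | Path) -> dict[str, EventStream]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    out = {}
    for actor, grp in df.groupby("actor"):
        grp = grp.sort_values("onset_ms")
        events = [
            Event(str(r.code), str(r.modality), int(r.onset_ms), int(r.offset_ms))
            for r in grp.itertuples()
        ]
        out[str(actor)] = EventStream(str(actor), events)
    return out


def write_gaze(path: str | Path, gaze: GazeEpisodes) -> None:
    pd.DataFrame(gaze.intervals, columns=["start_ms", "end_ms"]).to_csv(path, index=False)


def read_gaze(path: str | Path) -> GazeEpisodes:
    df = pd.read_csv(path)
    return GazeEpisodes([(int(r.start_ms), int(r.end_ms)) for r in df.itertuples()])


def write_touch(path: str | Path, record: TouchRecord) -> None:
    df = pd.DataFrame({"segment_index": range(len(record.codes)), "code": record.codes})
    with open(path, "w") as fh:
        fh.write(f"# video_duration_s={record.video_duration_s}\n")
        fh.write(f"# segment_s={record.segment_s}\n")
        df.to_csv(fh, index=False)


def read_touch(path: str | Path) -> TouchRecord:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, val = line[1:].strip().split("=", 1)
            meta[key] = float(val)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return TouchRecord(
        codes=[str(c) for c in df["code"]],
        video_duration_s=meta.get("video_duration_s", 2.0 * len(df)),
        segment_s=meta.get("segment_s", 2.0),
    )


# ---------------------------------------------------------------- SNIRF ----

def write_snirf(path: str | Path, rec: NirsRecording) -> None:
    """Write a recording as a minimal continuous-wave SNIRF file.

    One data block; measurement list ordered channel-major then wavelength,
    matching the in-memory (n_channels, 2, n_times) layout.  Annotations
    that SNIRF has no standard slot for (looking fractions, montage
    distances) go into metaDataTags as JSON strings.
    """
    n_ch, _, n_t = rec.intensity.shape
    flat = rec.intensity.reshape(n_ch * 2, n_t).T  # (n_t, n_meas)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("/nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times)
        for m in range(n_ch * 2):
            ch = m // 2
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=int(rec.montage.table["source"].iloc[ch]))
            ml.create_dataset("detectorIndex", data=int(rec.montage.table["detector"].iloc[ch]))
            ml.create_dataset("wavelengthIndex", data=m % 2 + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
        n_src = int(rec.montage.table["source"].max())
        n_det = int(rec.montage.table["detector"].max())
        probe.create_dataset("sourcePos3D", data=np.zeros((n_src, 3)))
        probe.create_dataset("detectorPos3D", data=np.zeros((n_det, 3)))
        for k, cond in enumerate(sorted(rec.markers["condition"].unique())):
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=cond)
            rows = rec.markers[rec.markers["condition"] == cond]
            onsets = rows["onset_s"].to_numpy(float)
            stim.create_dataset(
                "data", data=np.column_stack([onsets, np.full_like(onsets, 15.0),
                                              np.ones_like(onsets)])
            )
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="m")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("montage_json", data=rec.montage.table.to_json())
        meta.create_dataset("markers_json", data=rec.markers.to_json())
        meta.create_dataset("looking_json", data=rec.looking.to_json())
        if rec.brush_intervals is not None:
            meta.create_dataset("brush_json", data=json.dumps(rec.brush_intervals))


def read_snirf(path: str | Path) -> NirsRecording:
    with h5py.File(path, "r") as f:
        data = f["/nirs/data1"]
        flat = data["dataTimeSeries"][()]
        time = data["time"][()]
        fs = 1.0 / float(np.median(np.diff(time)))
        from io import StringIO

        meta = f["/nirs/metaDataTags"]
        montage = Montage(pd.read_json(StringIO(meta["montage_json"][()].decode())))
        markers = pd.read_json(StringIO(meta["markers_json"][()].decode()))
        looking = pd.read_json(StringIO(meta["looking_json"][()].decode()))
        brush = json.loads(meta["brush_json"][()].decode()) if "brush_json" in meta else None
        wavelengths = tuple(f["/nirs/probe/wavelengths"][()])
    n_ch = len(montage.table)
    intensity = flat.T.reshape(n_ch, 2, -1)
    return NirsRecording(
        intensity=intensity, fs=fs, montage=montage, markers=markers,
        looking=looking, wavelengths=wavelengths, brush_intervals=brush,
    )


# ------------------------------------------------------------- TSV dialect ----

def write_nirs_tsv(prefix: str | Path, rec: NirsRecording) -> tuple[Path, Path]:
    """Wide TSV (time + ch{c}_wl{w} columns) plus a JSON sidecar."""
    prefix = Path(prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    cols = {"time_s": rec.times}
    for ci, ch in enumerate(rec.montage.channels):
        for wi, wl in enumerate(rec.wavelengths):
            cols[f"ch{int(ch)}_wl{int(wl)}"] = rec.intensity[ci, wi]
    pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False)
    sidecar = {
        "fs": rec.fs,
        "wavelengths": list(rec.wavelengths),
        "montage": rec.montage.table.to_dict(orient="list"),
        "markers": rec.markers.to_dict(orient="list"),
        "looking": rec.looking.to_dict(orient="list"),
        "brush_intervals": rec.brush_intervals,
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return tsv_path, json_path


def read_nirs_tsv(prefix: str | Path) -> NirsRecording:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    montage = Montage(pd.DataFrame(sidecar["montage"]))
    wavelengths = tuple(sidecar["wavelengths"])
    n_t = len(df)
    intensity = np.empty((len(montage.table), 2, n_t))
    for ci, ch in enumerate(montage.channels):
        for wi, wl in enumerate(wavelengths):
            intensity[ci, wi] = df[f"ch{int(ch)}_wl{int(wl)}"].to_numpy()
    return NirsRecording(
        intensity=intensity,
        fs=float(sidecar["fs"]),
        montage=montage,
        markers=pd.DataFrame(sidecar["markers"]),
        looking=pd.DataFrame(sidecar["looking"]),
        wavelengths=wavelengths,
        brush_intervals=sidecar.get("brush_intervals"),
    )


def write_epochs_tsv(path: str | Path, subject: str, epochs) -> None:
    """Long epoch table: subject, roi, condition, time_s, HbO_uMol, HbR_uMol."""
    rows = []
    for (roi, cond), chans in epochs.epochs.items():
        hbo = chans["hbo"].mean(axis=0)
        hbr = chans["hbr"].mean(axis=0)
        for t, o, r in zip(epochs.times, hbo, hbr):
            rows.append((subject, roi, cond, float(t), float(o), float(r)))
    pd.DataFrame(
        rows, columns=["subject", "roi", "condition", "time_s", "HbO_uMol", "HbR_uMol"]
    ).to_csv(path, sep="\t", index=False)
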