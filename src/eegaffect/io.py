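"""Readers and writers for the formats the pipeline touches.

Signals travel as EDF (one file per participant-session, 16-bit, physical
dimension uV, channel labels = 10-20 montage names) or as a plain CSV
dialect (first column time in seconds, one column per channel, metadata in
``# key=value`` comment lines).  Events, responses, features and centroids
use tab-separated tables; cross-validation and statistics results use JSON.

EDF reading goes through MNE; writing uses a minimal built-in EDF encoder
(ASCII header + 16-bit little-endian samples, one 1 s data record per
second of signal).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .protocol import RESPONSE_COLUMNS, StimulusEvent, StimulusSchedule
from .synth import AffectGroundTruth, DeviceProfile, EEGRecording, EmotionTarget

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "condition", "stimulus_id",
    "face_sex", "with_music", "participant_id", "group", "session_index",
]


# ---------------------------------------------------------------- CSV signals

def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# participant_id={rec.participant_id}\n")
        fh.write(f"# group={rec.group}\n")
        fh.write(f"# session_index={rec.session_index}\n")
        fh.write(f"# sampling_rate_hz={rec.device.sampling_rate_hz}\n")
        fh.write("time_s," + ",".join(rec.device.channel_names) + "\n")
        times = rec.times
        for i in range(rec.n_samples):
            row = ",".join(f"{v:.6f}" for v in rec.data[:, i])
            fh.write(f"{times[i]:.6f},{row}\n")


def _csv_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_recording_csv(
    path: str | Path, device: DeviceProfile | None = None
) -> EEGRecording:
    path = Path(path)
    meta = _csv_metadata(path)
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    fs_meta = float(meta.get("sampling_rate_hz", 0)) or None
    fs = fs_meta if fs_meta else 1.0 / float(np.median(np.diff(t)))
    device = device or DeviceProfile(sampling_rate_hz=fs)
    if abs(device.sampling_rate_hz - fs) > 1e-6:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz does not match device profile "
            f"({device.sampling_rate_hz} Hz)"
        )
    channels = [c for c in df.columns if c != "time_s"]
    missing = [c for c in device.channel_names if c not in channels]
    if missing:
        raise ValueError(f"{path}: missing channel(s) {missing}")
    unknown = [c for c in channels if c not in device.channel_names]
    if unknown:
        raise ValueError(f"{path}: unknown channel label(s) {unknown}")
    data = np.vstack([df[c].to_numpy() for c in device.channel_names])
    return EEGRecording(
        participant_id=meta.get("participant_id", path.stem),
        group=meta.get("group", "EG"),
        session_index=int(meta.get("session_index", 1)),
        data=data,
        device=device,
        start_time_s=float(t[0]),
    )


# ---------------------------------------------------------------- EDF signals

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a plain EDF file: 16-bit samples, 1 s data records, uV units.

    The participant/recording identification fields carry the metadata the
    CSV dialect stores in comments.  The signal is zero-padded to a whole
    number of records; amplitudes are quantized to the per-channel 16-bit
    range (max absolute sample).
    """
    fs = rec.device.sampling_rate_hz
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.device.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    dig_max, dig_min = 32767, -32768
    scale = phys_max / dig_max
    digital = np.clip(
        np.round(padded / scale[:, None]), dig_min, dig_max
    ).astype("<i2")

    header = b""
    header += _edf_field("0", 8)
    # single token: MNE keeps only the first patient-field subfield
    header += _edf_field(f"{rec.participant_id}_{rec.group}_s{rec.session_index}", 80)
    header += _edf_field(f"session {rec.session_index}", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (n_ch + 1), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)

    def per_signal(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += per_signal(rec.device.channel_names, 16)
    header += per_signal([""] * n_ch, 80)
    header += per_signal(["uV"] * n_ch, 8)
    header += per_signal([f"{-m:.6g}"[:8] for m in phys_max], 8)
    header += per_signal([f"{m:.6g}"[:8] for m in phys_max], 8)
    header += per_signal([dig_min] * n_ch, 8)
    header += per_signal([dig_max] * n_ch, 8)
    header += per_signal([""] * n_ch, 80)
    header += per_signal([spr] * n_ch, 8)
    header += per_signal([""] * n_ch, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_recording_edf(
    path: str | Path, device: DeviceProfile | None = None
) -> EEGRecording:
    """Read an EDF recording via MNE; returns amplitudes in uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    device = device or DeviceProfile(sampling_rate_hz=fs)
    if abs(device.sampling_rate_hz - fs) > 1e-6:
        raise ValueError(
            f"{path}: sampling rate {fs} Hz does not match device profile "
            f"({device.sampling_rate_hz} Hz)"
        )
    missing = [c for c in device.channel_names if c not in raw.ch_names]
    if missing:
        raise ValueError(f"{path}: missing channel(s) {missing}")
    data = raw.get_data(picks=list(device.channel_names)) * 1e6  # V -> uV
    subject = (raw.info.get("subject_info") or {}).get("his_id", "") or ""
    parts = subject.split("_")
    pid = parts[0] if parts and parts[0] else Path(path).stem
    group = parts[1] if len(parts) > 1 and parts[1] in ("EG", "CG") else "EG"
    session = 1
    for token in parts[2:]:
        if token.startswith("s") and token[1:].isdigit():
            session = int(token[1:])
    return EEGRecording(
        participant_id=pid, group=group, session_index=session,
        data=data, device=device,
    )


def read_eeg(path: str | Path, device: DeviceProfile | None = None) -> EEGRecording:
    """Dispatch on file suffix: ``.edf`` or the CSV signal dialect."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, device)
    return read_recording_csv(path, device)


# ---------------------------------------------------------------- TSV tables

def write_events_tsv(schedule: StimulusSchedule, path: str | Path) -> None:
    rows = [
        (
            ev.onset_s, ev.duration_s, ev.emotion, ev.condition, ev.stimulus_id,
            ev.face_sex, ev.with_music, schedule.participant_id, schedule.group,
            schedule.session_index,
        )
        for ev in schedule.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path, transition_s: float = 5.0) -> StimulusSchedule:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "with_music"]
    if missing:
        raise ValueError(f"{path}: missing event column(s) {missing}")
    events = [
        StimulusEvent(
            onset_s=float(r.onset), duration_s=float(r.duration),
            emotion=str(r.trial_type), condition=str(r.condition),
            face_sex=str(r.face_sex), stimulus_id=str(r.stimulus_id),
        )
        for r in df.itertuples()
    ]
    first = df.iloc[0]
    return StimulusSchedule(
        participant_id=str(first["participant_id"]),
        group=str(first["group"]),
        session_index=int(first["session_index"]),
        events=events,
        transition_s=transition_s,
    )


def write_responses_tsv(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, sep="\t", index=False)


def read_responses_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing response column(s) {missing}")
    df["correct"] = df["correct"].astype(bool)
    return df[RESPONSE_COLUMNS]


def write_features_tsv(features: pd.DataFrame, path: str | Path) -> None:
    out = features.copy()
    out.attrs = {}
    header_note = features.attrs.get("normalization", "raw")
    with open(path, "w") as fh:
        fh.write(f"# normalization={header_note}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    meta = _csv_metadata(Path(path))
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {missing}")
    df.attrs["normalization"] = meta.get("normalization", "raw")
    return df


def write_ground_truth_tsv(truth: AffectGroundTruth, path: str | Path) -> None:
    rows = [(emo, t.arousal, t.valence) for emo, t in truth.items()]
    pd.DataFrame(
        rows, columns=["emotion", "target_arousal", "target_valence"]
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth_tsv(path: str | Path) -> AffectGroundTruth:
    df = pd.read_csv(path, sep="\t")
    return AffectGroundTruth({
        str(r.emotion): EmotionTarget(float(r.target_arousal), float(r.target_valence))
        for r in df.itertuples()
    })


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
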