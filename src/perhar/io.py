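"""Reading and writing recordings and segment sets.

Generic recording format: one delimited CSV per recording with one column
per channel plus a ``label`` column (an optional ``time`` column is ignored
for values but checked for monotonicity), and a YAML sidecar ``<name>.yaml``
carrying ``subject_id``, ``rate_hz`` and optionally ``recording_id``.

Adapters are provided for the file layouts of three public wearable
datasets; they are thin translations into :class:`ActivityRecording` and are
not exercised by the test suite against real downloads:

* MHEALTH: per-subject plain-text logs, 23 whitespace-separated sensor
  columns followed by an integer activity label.
* WISDM: raw ``user,activity_code,timestamp,x,y,z;`` accelerometer lines.
* SPAR: per-repetition CSV files named ``<subject>_<activity>_<side>_<rep>.csv``
  with 6 IMU channel columns.

Segment sets travel as ``.npz`` archives (windows, labels, subjects, source
ids, intervals, rate).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import ActivityRecording, Segment, SegmentSet


def write_recording(recording: ActivityRecording, directory, name: str | None = None) -> Path:
    """Write a recording as CSV + YAML sidecar; returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or recording.recording_id
    frame = pd.DataFrame(
        {f"ch{i}": recording.channels[i] for i in range(recording.n_channels)}
    )
    frame["label"] = recording.labels
    csv_path = directory / f"{name}.csv"
    frame.to_csv(csv_path, index=False)
    sidecar = {
        "subject_id": str(recording.subject_id),
        "rate_hz": float(recording.rate_hz),
        "recording_id": str(recording.recording_id),
    }
    (directory / f"{name}.yaml").write_text(yaml.safe_dump(sidecar))
    return csv_path


def read_recording(csv_path) -> ActivityRecording:
    """Read one CSV + YAML sidecar recording."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    frame = pd.read_csv(csv_path)
    if "label" not in frame.columns:
        raise ValueError(f"{csv_path} has no 'label' column")
    channel_cols = [c for c in frame.columns if c not in ("label", "time")]
    return ActivityRecording(
        subject_id=str(sidecar["subject_id"]),
        channels=frame[channel_cols].to_numpy().T,
        labels=frame["label"].to_numpy(),
        rate_hz=float(sidecar["rate_hz"]),
        recording_id=str(sidecar.get("recording_id", csv_path.stem)),
    )


def read_recording_dir(directory) -> list[ActivityRecording]:
    return [read_recording(p) for p in sorted(Path(directory).glob("*.csv"))]


def save_segments(segments: SegmentSet, path) -> None:
    np.savez_compressed(
        path,
        windows=segments.windows,
        labels=segments.labels,
        subjects=segments.subject_ids,
        sources=segments.source_ids,
        intervals=segments.intervals,
        rate_hz=np.array([segments.segments[0].rate_hz if len(segments) else 0.0]),
    )


def load_segments(path) -> SegmentSet:
    with np.load(path, allow_pickle=False) as data:
        rate = float(data["rate_hz"][0])
        out = []
        for i in range(data["windows"].shape[0]):
            out.append(
                Segment(
                    subject_id=str(data["subjects"][i]),
                    label=data["labels"][i],
                    window=data["windows"][i],
                    rate_hz=rate,
                    source_id=str(data["sources"][i]),
                    interval=(int(data["intervals"][i, 0]), int(data["intervals"][i, 1])),
                )
            )
    return SegmentSet(out)


# ---- public-dataset adapters -------------------------------------------------

MHEALTH_RATE_HZ = 50.0
WISDM_RATE_HZ = 20.0
SPAR_RATE_HZ = 50.0


def read_mhealth_log(path, subject_id: str | None = None) -> ActivityRecording:
    """MHEALTH ``mHealth_subjectN.log``: 23 sensor columns + label column."""
    path = Path(path)
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 24:
        raise ValueError("expected 24 whitespace-separated columns (23 channels + label)")
    return ActivityRecording(
        subject_id=subject_id or path.stem,
        channels=data[:, :23].T,
        labels=data[:, 23].astype(int),
        rate_hz=MHEALTH_RATE_HZ,
        recording_id=path.stem,
    )


def read_wisdm_raw(path) -> tuple[list[ActivityRecording], pd.DataFrame]:
    """WISDM raw txt: ``user,activity,timestamp,x,y,z;`` lines.

    Returns one recording per (user, contiguous activity order preserved)
    plus a duplicate-timestamp report (the published analyses excluded some
    subjects for absent or duplicated sensor readings; the detection rule was
    not specified, so the report is surfaced and no subject is dropped here).
    """
    path = Path(path)
    text = path.read_text()
    rows = []
    for line in text.replace(";", "\n").splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 6:
            continue
        rows.append(parts)
    frame = pd.DataFrame(rows, columns=["user", "activity", "timestamp", "x", "y", "z"])
    frame = frame.astype({"timestamp": np.int64, "x": float, "y": float, "z": float})
    dup_report = (
        frame.groupby("user")["timestamp"]
        .apply(lambda t: int(t.duplicated().sum()))
        .rename("duplicate_timestamps")
        .reset_index()
    )
    recordings = []
    for user, sub in frame.groupby("user", sort=True):
        sub = sub.sort_values("timestamp")
        recordings.append(
            ActivityRecording(
                subject_id=str(user),
                channels=sub[["x", "y", "z"]].to_numpy().T,
                labels=sub["activity"].to_numpy(),
                rate_hz=WISDM_RATE_HZ,
                recording_id=f"wisdm_{user}",
            )
        )
    return recordings, dup_report


def read_spar_csv(path) -> ActivityRecording:
    """SPAR per-repetition CSV named ``<subject>_<activity>_<side>_<rep>.csv``."""
    path = Path(path)
    parts = path.stem.split("_")
    if len(parts) < 2:
        raise ValueError("SPAR filenames encode subject and activity as S_A_side_rep")
    frame = pd.read_csv(path)
    numeric = frame.select_dtypes("number")
    return ActivityRecording(
        subject_id=parts[0],
        channels=numeric.to_numpy().T,
        labels=np.full(len(frame), parts[1]),
        rate_hz=SPAR_RATE_HZ,
        recording_id=path.stem,
    )
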