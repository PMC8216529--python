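"""Reading and writing the package's on-disk formats (recording CSVs, manifests)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from musclenet.synthetic import EmgRecording


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path


def write_recording_csv(rec: EmgRecording, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, label in enumerate(rec.channel_labels):
        df[label] = rec.samples[i]
    df.to_csv(path, index=False)
    return path


def read_recording_csv(
    path, subject_id: str, group: str, task: str, trial: int, fs: float
) -> EmgRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    labels = tuple(c for c in df.columns if c != "time_s")
    samples = df[list(labels)].to_numpy().T
    return EmgRecording(
        subject_id=subject_id,
        group=group,
        task=task,
        trial_index=trial,
        fs=fs,
        channel_labels=labels,
        samples=samples,
    )


def read_manifest(manifest_path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "task", "trial", "fs_hz", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        if not (Path(manifest_path).parent / row["path"]).exists():
            raise ValueError(
                f"{manifest_path}: line {i + 2}: recording file not found: {row['path']}"
            )
    return df


def load_cohort(manifest_path) -> list[EmgRecording]:
    """Load every recording listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    recs = []
    for _, row in df.iterrows():
        recs.append(
            read_recording_csv(
                manifest_path.parent / row["path"],
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                task=str(row["task"]),
                trial=int(row["trial"]),
                fs=float(row["fs_hz"]),
            )
        )
    return recs


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
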