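"""Tab-separated annotation/match tables and 16-bit PCM WAV audio."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .recognizer import Match
from .scenes import Recording, TrueCall

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_matches",
    "write_matches",
    "read_wav",
    "write_wav",
    "load_config_file",
]

ANNOTATION_COLUMNS = ["recording_id", "start_s", "end_s", "n_syllables", "site_id", "year"]
MATCH_COLUMNS = ["recording_id", "start_s", "end_s", "score", "label"]

_TIME_DECIMALS = 6  # times round-trip at microsecond precision


def write_annotations(calls: list[TrueCall], path) -> None:
    df = pd.DataFrame(
        {
            "recording_id": [c.recording_id for c in calls],
            "start_s": [round(c.start_s, _TIME_DECIMALS) for c in calls],
            "end_s": [round(c.end_s, _TIME_DECIMALS) for c in calls],
            "n_syllables": [c.n_syllables for c in calls],
            "site_id": [c.site_id for c in calls],
            "year": [c.year_label for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[TrueCall]:
    df = pd.read_csv(path, sep="\t", dtype={"recording_id": str, "site_id": str, "year": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    calls = []
    for i, row in df.iterrows():
        if row["end_s"] <= row["start_s"]:
            raise ValueError(f"row {i}: end_s must exceed start_s")
        if not 1 <= int(row["n_syllables"]) <= 4:
            raise ValueError(f"row {i}: n_syllables out of range 1..4")
        calls.append(
            TrueCall(
                recording_id=str(row["recording_id"]),
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                n_syllables=int(row["n_syllables"]),
                site_id=str(row["site_id"]),
                year_label=str(row["year"]),
            )
        )
    return calls


def write_matches(matches: list[Match], path) -> None:
    df = pd.DataFrame(
        {
            "recording_id": [m.recording_id for m in matches],
            "start_s": [round(m.start_s, _TIME_DECIMALS) for m in matches],
            "end_s": [round(m.end_s, _TIME_DECIMALS) for m in matches],
            "score": [m.score for m in matches],
            "label": [m.label for m in matches],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_matches(path) -> list[Match]:
    df = pd.read_csv(path, sep="\t", dtype={"recording_id": str, "label": str})
    missing = set(MATCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"match table missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        if row["end_s"] <= row["start_s"]:
            raise ValueError(f"row {i}: end_s must exceed start_s")
        out.append(
            Match(
                recording_id=str(row["recording_id"]),
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                score=float(row["score"]),
                label=str(row["label"]),
            )
        )
    return out


def write_wav(recording: Recording, path) -> None:
    """Write mono 16-bit PCM; float samples are clipped to [-1, 1)."""
    x = np.clip(recording.samples, -1.0, 32767.0 / 32768.0)
    wavfile.write(path, recording.sample_rate_hz, (x * 32768.0).astype(np.int16))


def read_wav(path, recording_id: str | None = None, **meta) -> Recording:
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    else:
        samples = data.astype(np.float64)
    rid = recording_id if recording_id is not None else Path(path).stem
    return Recording(
        recording_id=rid,
        site_id=meta.get("site_id", ""),
        year_label=meta.get("year_label", ""),
        group_label=meta.get("group_label", ""),
        sample_rate_hz=int(fs),
        samples=samples,
    )


def load_config_file(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
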