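"""Readers and writers for the plain formats the toolkit consumes.

Continuous signals travel as delimited text (first column time, one
column per channel, header row of labels), as ``.npy`` array containers,
or as 16-bit PCM WAV (audio, force).  Tap logs are delimited text with
``participant, trial, condition, onset_s`` columns.  EEG acquisition
formats (EDF/BrainVision) are out of scope here; recordings arrive
already converted/cleaned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .behavior import TapTrial
from .signal import ContinuousRecording

__all__ = [
    "write_recording_txt",
    "read_recording_txt",
    "write_recording_npy",
    "read_recording_npy",
    "write_wav",
    "read_wav",
    "write_tap_log",
    "read_tap_log",
]


def write_recording_txt(rec: ContinuousRecording, path, sep: str = "\t") -> None:
    t = rec.t0_s + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for label, row in zip(rec.channel_labels, rec.samples):
        df[label] = row
    df.to_csv(path, sep=sep, index=False)


def read_recording_txt(path, sep: str = "\t") -> ContinuousRecording:
    df = pd.read_csv(path, sep=sep)
    t = df.iloc[:, 0].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need >= 2 samples to infer fs")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError(f"{path}: non-uniform time column")
    return ContinuousRecording(
        samples=df.iloc[:, 1:].to_numpy().T,
        fs=1.0 / dt.mean(),
        channel_labels=list(df.columns[1:]),
        t0_s=float(t[0]),
    )


def write_recording_npy(rec: ContinuousRecording, path) -> None:
    np.save(
        path,
        {
            "samples": rec.samples,
            "fs": rec.fs,
            "channel_labels": rec.channel_labels,
            "t0_s": rec.t0_s,
        },
        allow_pickle=True,
    )


def read_recording_npy(path) -> ContinuousRecording:
    d = np.load(path, allow_pickle=True).item()
    return ContinuousRecording(**d)


def write_wav(signal, fs: float, path) -> None:
    x = np.asarray(signal, dtype=float).squeeze()
    peak = np.max(np.abs(x)) or 1.0
    wavfile.write(path, int(fs), np.asarray(x / peak * 32767, dtype=np.int16))


def read_wav(path) -> ContinuousRecording:
    fs, x = wavfile.read(path)
    if x.dtype == np.int16:
        x = x / 32768.0
    return ContinuousRecording(samples=np.atleast_2d(x.T), fs=float(fs))


def write_tap_log(trials_by_participant: dict, path, sep: str = ",") -> None:
    """``trials_by_participant``: {participant id: [TapTrial, ...]}."""
    rows = []
    for pid, trials in trials_by_participant.items():
        for t in trials:
            cond = t.condition.index if t.condition is not None else 0
            for onset in t.onsets_s:
                rows.append((pid, t.trial, cond, onset))
    pd.DataFrame(
        rows, columns=["participant", "trial", "condition", "onset_s"]
    ).to_csv(path, sep=sep, index=False)


def read_tap_log(path, conditions=None, sep: str = ",") -> dict:
    """Inverse of :func:`write_tap_log`; ``conditions`` (index ->
    RhythmCondition) rehydrates the condition objects when given."""
    df = pd.read_csv(path, sep=sep)
    by_cond = {c.index: c for c in conditions} if conditions is not None else {}
    out: dict = {}
    for (pid, trial, cond), grp in df.groupby(
        ["participant", "trial", "condition"], sort=True
    ):
        out.setdefault(pid, []).append(
            TapTrial(
                onsets_s=np.sort(grp["onset_s"].to_numpy()),
                condition=by_cond.get(cond),
                trial=int(trial),
            )
        )
    return out
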