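"""Deterministic conditioning of continuous signals.

Filtering, epoching, demeaning, averaging, decimation and impulse-train
construction — the steps that turn raw multichannel recordings (EEG,
tapping force) or tap-onset logs into trial-averaged response cycles.
All operations are deterministic and channel-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "butterworth",
    "segment_epochs",
    "demean_epochs",
    "average_epochs",
    "downsample",
    "impulse_train",
]


@dataclass
class ContinuousRecording:
    """Channels-by-time amplitude values at a fixed sampling rate.

    ``t0_s`` is the time of the first sample relative to stimulus-sequence
    onset (negative for pre-stimulus baseline segments).
    """

    samples: np.ndarray
    fs: float
    channel_labels: list = field(default_factory=list)
    t0_s: float = 0.0
    lowpassed: bool = False  # set by butterworth(kind="low"); read by downsample

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel label count must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def pick(self, labels) -> "ContinuousRecording":
        """Channel subset in the requested order."""
        idx = [self.channel_labels.index(l) for l in labels]
        return replace(
            self, samples=self.samples[idx], channel_labels=list(labels)
        )


@dataclass
class EpochSet:
    """n_epochs x channels x samples array of fixed-length epochs."""

    epochs: np.ndarray
    epoch_dur_s: float
    fs: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, channels, samples)")
        expect = int(round(self.epoch_dur_s * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != expect:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != round(dur*fs) = {expect}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def butterworth(
    rec: ContinuousRecording, kind: str, order: int = 4, cutoff_hz: float = 10.0
) -> ContinuousRecording:
    """Zero-phase Butterworth filter (forward-backward, so no group delay;
    effective attenuation is the squared magnitude response)."""
    if kind not in ("low", "high"):
        raise ValueError(f"kind must be 'low' or 'high', got {kind!r}")
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(
            f"cutoff_hz={cutoff_hz} must lie in (0, Nyquist={rec.fs / 2})"
        )
    sos = sps.butter(order, cutoff_hz, btype=kind, fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered, lowpassed=rec.lowpassed or kind == "low")


def segment_epochs(
    rec: ContinuousRecording,
    start_s: float,
    epoch_dur_s: float,
    n_epochs: int,
    baseline_window_s: tuple | None = None,
) -> EpochSet:
    """Cut contiguous, non-overlapping epochs of ``epoch_dur_s`` seconds.

    Epoch k starts at sample ``round((start_s + k*epoch_dur_s - t0_s) * fs)``.
    ``baseline_window_s = (b0, b1)`` (relative to sequence onset) subtracts
    the per-channel mean over that window from the whole recording first
    (force-channel offset correction).
    """
    samples = rec.samples
    if baseline_window_s is not None:
        b0, b1 = baseline_window_s
        i0 = int(round((b0 - rec.t0_s) * rec.fs))
        i1 = int(round((b1 - rec.t0_s) * rec.fs))
        if not 0 <= i0 < i1 <= rec.n_samples:
            raise ValueError(f"baseline window {baseline_window_s} outside recording")
        samples = samples - samples[:, i0:i1].mean(axis=1, keepdims=True)
    n_len = int(round(epoch_dur_s * rec.fs))
    epochs = np.empty((n_epochs, rec.n_channels, n_len))
    for k in range(n_epochs):
        i0 = int(round((start_s + k * epoch_dur_s - rec.t0_s) * rec.fs))
        i1 = i0 + n_len
        if i0 < 0 or i1 > rec.n_samples:
            raise ValueError(
                f"epoch {k} needs samples [{i0}, {i1}) but recording has "
                f"{rec.n_samples}; short by {max(0, i1 - rec.n_samples)} samples"
            )
        epochs[k] = samples[:, i0:i1]
    return EpochSet(epochs=epochs, epoch_dur_s=epoch_dur_s, fs=rec.fs)


def demean_epochs(e: EpochSet) -> EpochSet:
    """Subtract each epoch/channel's own temporal mean (offset correction)."""
    if e.n_epochs == 0:
        return e
    out = e.epochs - e.epochs.mean(axis=2, keepdims=True)
    return EpochSet(epochs=out, epoch_dur_s=e.epoch_dur_s, fs=e.fs)


def average_epochs(e: EpochSet) -> np.ndarray:
    """Pointwise mean across epochs -> (channels, samples); attenuates
    activity not phase-locked to the pattern."""
    if e.n_epochs < 1:
        raise ValueError("cannot average an empty epoch set")
    return e.epochs.mean(axis=0)


def downsample(rec: ContinuousRecording, factor: int) -> ContinuousRecording:
    """Keep every ``factor``-th sample.  Plain decimation: the caller must
    have band-limited the signal below the new Nyquist (a prior low-pass
    via :func:`butterworth` silences the warning)."""
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return rec
    if not rec.lowpassed:
        warnings.warn(
            "downsampling a recording with no recorded low-pass; aliasing is "
            "the caller's responsibility",
            stacklevel=2,
        )
    return replace(rec, samples=rec.samples[:, ::factor], fs=rec.fs / factor)


def impulse_train(
    onsets_s, fs: float, duration_s: float, label: str = "impulse"
) -> ContinuousRecording:
    """Single-channel unit-impulse train: sample ``round(onset*fs)`` set to
    1, 0 elsewhere; coincident onsets still give value 1."""
    onsets = np.asarray(onsets_s, dtype=float)
    n = int(round(duration_s * fs))
    if onsets.size and (onsets.min() < 0 or onsets.max() >= duration_s):
        bad = onsets[(onsets < 0) | (onsets >= duration_s)]
        raise ValueError(f"onsets outside [0, {duration_s}): {bad[:5]}")
    x = np.zeros(n)
    if onsets.size:
        idx = np.minimum(np.round(onsets * fs).astype(int), n - 1)
        x[idx] = 1.0
    return ContinuousRecording(samples=x[None, :], fs=fs, channel_labels=[label])
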