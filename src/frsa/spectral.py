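"""Frequency-tagging feature extraction.

A periodic stimulus elicits responses concentrated at the pattern
repetition rate f0 = 1/pattern_s and its integer harmonics.  This module
computes complex FFT spectra of trial-averaged signals, selects harmonic
frequencies of interest (FOIs), z-scores magnitudes against the local
noise floor in neighboring bins, assembles re/im coefficient feature
vectors for RSA, and noise-corrects magnitudes for prototype matching.

FFT normalization convention: coefficients are divided by the number of
samples, so a unit-amplitude cosine at an exact bin has magnitude 0.5.
The convention cancels in every correlation and z-score downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComplexSpectrum",
    "FrequencySet",
    "fft_spectrum",
    "harmonic_frequencies",
    "snr_zscore",
    "consecutive_significant",
    "feature_vector",
    "noise_corrected_magnitudes",
]

#: one-tailed P < 0.001 on the standard normal
Z_CRIT = 3.09


@dataclass
class ComplexSpectrum:
    """Channels x frequency-bin complex Fourier coefficients."""

    coefficients: np.ndarray
    fs: float
    n_samples: int
    channel_labels: list

    @property
    def df_hz(self) -> float:
        """Frequency resolution (bin spacing) = fs / n_samples."""
        return self.fs / self.n_samples

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def freq_of_bin(self, k) -> np.ndarray:
        return np.asarray(k) * self.df_hz


@dataclass
class FrequencySet:
    """Harmonics of the pattern-repetition rate retained as features."""

    f0_hz: float
    harmonics: np.ndarray
    bin_indices: np.ndarray

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.harmonics * self.f0_hz

    @property
    def n(self) -> int:
        return len(self.harmonics)

    def subset(self, n_keep: int) -> "FrequencySet":
        return FrequencySet(
            f0_hz=self.f0_hz,
            harmonics=self.harmonics[:n_keep],
            bin_indices=self.bin_indices[:n_keep],
        )


def fft_spectrum(signal, fs: float, channel_labels=None) -> ComplexSpectrum:
    """Discrete Fourier transform of a (channels, samples) or 1-D signal;
    no windowing, coefficients normalized by the sample count."""
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n = x.shape[1]
    if n < 2:
        raise ValueError("signal must have length >= 2")
    coeff = np.fft.rfft(x, axis=1) / n
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(x.shape[0])]
    return ComplexSpectrum(
        coefficients=coeff, fs=fs, n_samples=n, channel_labels=list(channel_labels)
    )


def harmonic_frequencies(
    pattern_s: float, f_max_hz: float, df_hz: float, tol: float = 1e-6
) -> FrequencySet:
    """Harmonics k*f0 for k = 1..floor(f_max*pattern_s), mapped to spectrum
    bins.  Each harmonic must land on an exact bin (the analyzed signal is
    an integer number of pattern cycles); a mismatch beyond ``tol * df``
    is rejected."""
    if pattern_s <= 0:
        raise ValueError(f"pattern_s must be positive, got {pattern_s}")
    f0 = 1.0 / pattern_s
    if f_max_hz < f0:
        raise ValueError(f"f_max_hz={f_max_hz} below f0={f0}")
    harmonics = np.arange(1, int(np.floor(f_max_hz * pattern_s)) + 1)
    freqs = harmonics * f0
    bins_float = freqs / df_hz
    bins = np.round(bins_float).astype(int)
    err = np.abs(bins_float - bins) * df_hz
    if np.any(err > tol * df_hz):
        raise ValueError(
            "harmonics do not fall on exact frequency bins (sequence is not "
            f"an integer number of cycles): max offset {err.max():.3g} Hz"
        )
    return FrequencySet(f0_hz=f0, harmonics=harmonics, bin_indices=bins)


def _baseline_offsets(n_flank: int, skip: int) -> np.ndarray:
    off = np.arange(skip + 1, skip + n_flank + 1)
    return np.concatenate([-off[::-1], off])


def snr_zscore(
    mag, bin: int, n_flank: int = 4, skip: int = 1
) -> float:
    """z-score of a magnitude bin against the local noise baseline.

    Baseline = ``n_flank`` bins on each side at offsets skip+1..skip+n_flank
    (the immediately adjacent ``skip`` bins are excluded against residual
    spectral leakage).  z = (x - mean(baseline)) / SD(baseline) with the
    sample SD (n-1).  A zero-SD baseline yields NaN, never +/-inf.
    """
    mag = np.asarray(mag, dtype=float).ravel()
    off = _baseline_offsets(n_flank, skip)
    idx = bin + off
    if idx.min() < 0 or idx.max() >= mag.size:
        raise ValueError(
            f"bin {bin} lacks {n_flank}+{skip} valid neighbors on each side"
        )
    bl = mag[idx]
    sd = bl.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((mag[bin] - bl.mean()) / sd)


def consecutive_significant(
    z_per_harmonic, z_crit: float = Z_CRIT
) -> np.ndarray:
    """Indices (1-based harmonic numbers) of the unbroken run of
    significant harmonics starting at harmonic 1; empty if the first
    harmonic is not significant."""
    z = np.asarray(z_per_harmonic, dtype=float)
    keep = z > z_crit
    m = 0
    while m < keep.size and keep[m]:
        m += 1
    return np.arange(1, m + 1)


def feature_vector(
    spectrum: ComplexSpectrum, fois: FrequencySet, channels=None
) -> np.ndarray:
    """Concatenate real and imaginary coefficients at the FOIs into one
    vector: FOI-major, re before im, channels innermost; length =
    n_foi * 2 * n_channels."""
    if channels is None:
        chan_idx = np.arange(len(spectrum.channel_labels))
    else:
        missing = [c for c in channels if c not in spectrum.channel_labels]
        if missing:
            raise ValueError(f"channels not in spectrum: {missing}")
        chan_idx = np.array([spectrum.channel_labels.index(c) for c in channels])
    bins = np.asarray(fois.bin_indices)
    if bins.max() >= spectrum.coefficients.shape[1]:
        raise ValueError("FOI bin outside spectrum")
    coeff = spectrum.coefficients[np.ix_(chan_idx, bins)]  # (chan, foi)
    parts = []
    for f in range(bins.size):
        parts.append(coeff[:, f].real)
        parts.append(coeff[:, f].imag)
    return np.concatenate(parts)


def noise_corrected_magnitudes(
    mag, fois: FrequencySet, n_flank: int = 4, skip: int = 1
) -> np.ndarray:
    """Magnitude at each FOI minus the mean of its local-baseline bins
    (same bins as :func:`snr_zscore`); negative values are kept."""
    mag = np.asarray(mag, dtype=float).ravel()
    off = _baseline_offsets(n_flank, skip)
    out = np.empty(fois.n)
    for i, b in enumerate(fois.bin_indices):
        idx = b + off
        if idx.min() < 0 or idx.max() >= mag.size:
            raise ValueError(f"FOI bin {b} lacks full flanks")
        out[i] = mag[b] - mag[idx].mean()
    return out
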