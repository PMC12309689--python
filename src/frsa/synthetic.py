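"""Synthetic tapping and EEG-like datasets with known ground truth.

The generator states a world in which rhythm categorization is real and
its parameters are known, so every pipeline stage can be tested for
recovery: produced rhythms are warped toward a category attractor
(``produced_r = (1-w) * stimulus_r + w * attractor``), taps carry
Gaussian timing jitter, a constant negative anticipation (asynchrony),
and occasional misses/extra taps; EEG-like trials are the warped impulse
train convolved with a gamma-shaped response kernel, scaled by a
frontocentral topography, in 1/f plus alpha-band noise over 64 channels.

Defaults mirror the experimental design being emulated: a 13-condition
continuum (0.50-2/3, 750-ms pattern, 30 cycles, 22.5-s trials), 18
participants, 3 tapping / 6 EEG trials per condition, category attractors
at 0.53 and 0.63 with the boundary after condition 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behavior import TapTrial
from .design import RhythmCondition, build_sequence, make_condition_continuum
from .signal import ContinuousRecording, impulse_train

__all__ = [
    "SimulationSpec",
    "EEG_CHANNELS_64",
    "FRONTOCENTRAL_9",
    "simulate_tap_participant",
    "simulate_eeg_participant",
    "simulate_null_participant",
]

# 64-channel 10-10 montage (mastoids excluded), frontocentral pool included
EEG_CHANNELS_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz", "F9", "F10",
]
FRONTOCENTRAL_9 = ["F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2"]


@dataclass
class SimulationSpec:
    """Stated world for the simulators; see module docstring for defaults."""

    design: list = None  # condition continuum; built if None
    boundary_after: int = 5
    proto_small: float = 0.53
    proto_big: float = 0.63
    warp_strength: float = 0.8
    timing_sd_s: float = 0.010
    asynchrony_mean_s: float = -0.030
    miss_rate: float = 0.02
    extra_rate: float = 0.02
    n_cycles: int = 30
    n_trials_tap: int = 3
    n_trials_eeg: int = 6
    n_participants: int = 18
    fs: float = 256.0
    # EEG response kernel: gamma-shaped, peaking at kernel_peak_s
    kernel_peak_s: float = 0.100
    kernel_shape: float = 2.0
    # noise model
    one_over_f_exponent: float = 1.0
    noise_amp: float = 7.0
    alpha_amp: float = 4.0
    channels: list = field(default_factory=lambda: list(EEG_CHANNELS_64))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = make_condition_continuum()
        for name in ("warp_strength", "miss_rate", "extra_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.timing_sd_s < 0:
            raise ValueError("timing_sd_s must be >= 0")

    def attractor(self, condition: RhythmCondition) -> float:
        return (
            self.proto_small
            if condition.index <= self.boundary_after
            else self.proto_big
        )

    def produced_ratio(self, condition: RhythmCondition) -> float:
        w = self.warp_strength
        return (1.0 - w) * condition.r + w * self.attractor(condition)


def _rng(spec: SimulationSpec, participant_seed: int, stream: int):
    return np.random.default_rng([spec.seed, int(participant_seed), stream])


def _warped_event_times(spec: SimulationSpec, condition: RhythmCondition) -> np.ndarray:
    T = condition.pattern_s
    rho = spec.produced_ratio(condition)
    starts = np.arange(spec.n_cycles) * T
    return np.sort(np.concatenate([starts, starts + rho * T]))


def simulate_tap_participant(
    spec: SimulationSpec, participant_seed: int
) -> list[TapTrial]:
    """Tap trials for one participant: warped, jittered, anticipating,
    with misses and extra taps.  Bit-reproducible for a given
    (spec.seed, participant_seed)."""
    rng = _rng(spec, participant_seed, 0)
    trials = []
    for cond in spec.design:
        duration = spec.n_cycles * cond.pattern_s
        for tr in range(spec.n_trials_tap):
            taps = _warped_event_times(spec, cond) + spec.asynchrony_mean_s
            taps = taps + rng.normal(0.0, spec.timing_sd_s, size=taps.size)
            keep = rng.random(taps.size) >= spec.miss_rate
            taps = taps[keep]
            n_extra = rng.binomial(spec.n_cycles, spec.extra_rate)
            if n_extra:
                taps = np.concatenate([taps, rng.uniform(0, duration, n_extra)])
            taps = np.unique(taps[(taps >= 0) & (taps < duration)])
            trials.append(TapTrial(onsets_s=taps, condition=cond, trial=tr))
    return trials


def _gamma_kernel(spec: SimulationSpec, fs: float) -> np.ndarray:
    """Gamma-shaped impulse response, unit peak, ~0.5 s support."""
    scale = spec.kernel_peak_s / max(spec.kernel_shape - 1.0, 1e-6)
    t = np.arange(0, 0.5, 1.0 / fs)
    k = stats.gamma.pdf(t, a=spec.kernel_shape, scale=scale)
    return k / k.max()


def _pink_noise(rng, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent amplitude-shaped Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _alpha_noise(rng, n: int, fs: float) -> np.ndarray:
    """Band-limited (8-12 Hz) Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < 8.0) | (f > 12.0)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _channel_gains(spec: SimulationSpec) -> np.ndarray:
    """Fixed frontocentral-maximum topography: gain 1 over the 9-channel
    pool, 0.35 elsewhere with a deterministic ripple."""
    gains = np.empty(len(spec.channels))
    for i, ch in enumerate(spec.channels):
        base = 1.0 if ch in FRONTOCENTRAL_9 else 0.35
        gains[i] = base * (1.0 + 0.05 * np.sin(i))
    return gains


def simulate_eeg_participant(
    spec: SimulationSpec, participant_seed: int
) -> dict[int, list[ContinuousRecording]]:
    """EEG-like recordings, ``{condition index: [trial recordings]}``.

    Each trial: warped impulse train convolved with the gamma kernel,
    scaled per channel by the frontocentral topography, plus 1/f and
    alpha-band noise (independent per channel and trial).
    """
    rng = _rng(spec, participant_seed, 1)
    fs = spec.fs
    kernel = _gamma_kernel(spec, fs)
    gains = _channel_gains(spec)
    out: dict[int, list[ContinuousRecording]] = {}
    for cond in spec.design:
        duration = spec.n_cycles * cond.pattern_s
        n = int(round(duration * fs))
        events = _warped_event_times(spec, cond)
        base = impulse_train(events, fs, duration).samples[0]
        # circular convolution = steady state of the seamless loop, so the
        # noiseless response is exactly periodic (no onset transient)
        k_pad = np.zeros(n)
        k_pad[: kernel.size] = kernel
        evoked = np.fft.irfft(np.fft.rfft(base) * np.fft.rfft(k_pad), n)
        recs = []
        for _ in range(spec.n_trials_eeg):
            noise = np.empty((gains.size, n))
            for c in range(gains.size):
                noise[c] = spec.noise_amp * _pink_noise(
                    rng, n, spec.one_over_f_exponent
                ) + spec.alpha_amp * _alpha_noise(rng, n, fs)
            samples = gains[:, None] * evoked[None, :] + noise
            recs.append(
                ContinuousRecording(
                    samples=samples, fs=fs, channel_labels=list(spec.channels)
                )
            )
        out[cond.index] = recs
    return out


def simulate_null_participant(
    spec: SimulationSpec, participant_seed: int, kind: str = "tap"
):
    """Same generative process with warp_strength forced to 0: the
    response tracks the stimulus exactly, so any apparent categorical
    structure is a false positive (type-I calibration)."""
    import dataclasses

    null_spec = dataclasses.replace(spec, warp_strength=0.0, design=spec.design)
    if kind == "tap":
        return simulate_tap_participant(null_spec, participant_seed)
    if kind == "eeg":
        return simulate_eeg_participant(null_spec, participant_seed)
    raise ValueError(f"kind must be 'tap' or 'eeg', got {kind!r}")
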