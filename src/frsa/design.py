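"""Stimulus design: the two-interval rhythm continuum and categorical models.

A two-interval rhythmic pattern presents two tone onsets per repeating cycle
of fixed duration ``pattern_s``.  The pattern is summarized by the interval
ratio ``r = IOI1 / (IOI1 + IOI2)`` — the first inter-onset interval relative
to the whole pattern; ``r = 0.5`` is the isochronous 1:1 rhythm and
``r = 2/3`` the 2:1 rhythm.  A condition continuum linearly interpolates
between two such ratios.  Theoretical categorical models are binary
similarity matrices that split the continuum at a candidate category
boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rsm import RSM

__all__ = [
    "RhythmCondition",
    "StimulusSequence",
    "ToneSpec",
    "CategoricalModelRSM",
    "make_condition_continuum",
    "build_sequence",
    "render_audio",
    "acoustic_rsm",
    "categorical_model_set",
    "boundary_ratio",
    "design_to_json",
    "design_from_json",
]

_RTOL = 1e-9


@dataclass(frozen=True)
class RhythmCondition:
    """One point on the two-interval continuum.

    Parameters
    ----------
    index : int
        1-based ordinal position on the continuum.
    r : float
        First-interval ratio IOI1 / pattern duration, in (0, 1).
    pattern_s : float
        Pattern (cycle) duration in seconds.
    """

    index: int
    r: float
    pattern_s: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"r must lie in (0, 1), got r={self.r}")
        if self.pattern_s <= 0:
            raise ValueError(f"pattern_s must be positive, got {self.pattern_s}")

    @property
    def ioi1_s(self) -> float:
        return self.r * self.pattern_s

    @property
    def ioi2_s(self) -> float:
        return (1.0 - self.r) * self.pattern_s


@dataclass(frozen=True)
class StimulusSequence:
    """A rhythm condition looped seamlessly for a number of cycles.

    Two tone onsets per cycle, at ``k * pattern_s`` and
    ``k * pattern_s + r * pattern_s``; the third tone of a cycle is the
    first tone of the next.
    """

    condition: RhythmCondition
    n_cycles: int
    event_times_s: tuple = field(repr=False, default=())

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.condition.pattern_s

    def tone_times(self, include_final: bool = False) -> np.ndarray:
        """All tone-onset times; optionally append the onset closing the
        final cycle (start of the never-played cycle ``n_cycles``)."""
        t = np.asarray(self.event_times_s, dtype=float)
        if include_final:
            t = np.append(t, self.duration_s)
        return t


@dataclass(frozen=True)
class ToneSpec:
    """Pure-tone parameters: carrier frequency, duration, linear on/off ramp."""

    carrier_hz: float = 300.0
    dur_s: float = 0.050
    ramp_s: float = 0.010

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValueError(f"carrier_hz must be positive, got {self.carrier_hz}")
        if 2 * self.ramp_s > self.dur_s:
            raise ValueError(
                f"2*ramp_s ({2 * self.ramp_s}) must not exceed dur_s ({self.dur_s})"
            )


class CategoricalModelRSM(RSM):
    """Binary two-category theoretical RSM.

    Entry (i, j) is 1 iff conditions i and j fall on the same side of the
    category boundary.  ``boundary_after`` is the 1-based index of the last
    condition belonging to the first (smaller-ratio) category.
    """

    def __init__(self, boundary_after: int, n_conditions: int):
        if not 2 <= boundary_after <= n_conditions - 2:
            raise ValueError(
                "each category must span >= 2 conditions: "
                f"boundary_after={boundary_after}, n_conditions={n_conditions}"
            )
        side = np.arange(1, n_conditions + 1) <= boundary_after
        matrix = (side[:, None] == side[None, :]).astype(float)
        super().__init__(matrix, kind="binary")
        self.boundary_after = boundary_after


def make_condition_continuum(
    n: int = 13,
    r_start: float = 0.5,
    r_end: float = 2.0 / 3.0,
    pattern_s: float = 0.75,
) -> list[RhythmCondition]:
    """Linearly spaced interval-ratio continuum, endpoints included.

    The default reproduces a 13-condition continuum between the 1:1
    (r = 0.50) and the 2:1 (r = 2/3) rhythm with a 750-ms pattern.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got n={n}")
    if not 0.0 < r_start < r_end < 1.0:
        raise ValueError(
            f"require 0 < r_start < r_end < 1, got r_start={r_start}, r_end={r_end}"
        )
    ratios = np.linspace(r_start, r_end, n)
    return [
        RhythmCondition(index=i + 1, r=float(r), pattern_s=pattern_s)
        for i, r in enumerate(ratios)
    ]


def build_sequence(condition: RhythmCondition, n_cycles: int = 30) -> StimulusSequence:
    """Loop a condition's pattern seamlessly for ``n_cycles`` cycles."""
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    T = condition.pattern_s
    starts = np.arange(n_cycles) * T
    events = np.sort(np.concatenate([starts, starts + condition.r * T]))
    return StimulusSequence(
        condition=condition, n_cycles=n_cycles, event_times_s=tuple(events)
    )


def render_audio(
    sequence: StimulusSequence,
    tone: ToneSpec | None = None,
    fs: float = 44100.0,
    peak: float = 0.9,
) -> np.ndarray:
    """Render the sequence as audio: each event a ramped pure tone, silence
    elsewhere.  Peak amplitude normalized to ``peak`` full scale."""
    tone = tone or ToneSpec()
    if fs < 2 * tone.carrier_hz:
        raise ValueError(
            f"fs={fs} undersamples the {tone.carrier_hz}-Hz carrier (need >= 2x)"
        )
    events = np.asarray(sequence.event_times_s, dtype=float)
    if events.size > 1:
        min_ioi = float(np.min(np.diff(events)))
        if tone.dur_s >= min_ioi:
            raise ValueError(
                f"tone duration {tone.dur_s}s overlaps the shortest IOI {min_ioi}s"
            )
    n_total = int(round(sequence.duration_s * fs))
    out = np.zeros(n_total)
    n_tone = int(round(tone.dur_s * fs))
    t = np.arange(n_tone) / fs
    env = np.minimum(
        1.0,
        np.minimum(t / tone.ramp_s, (tone.dur_s - t) / tone.ramp_s)
        if tone.ramp_s > 0
        else 1.0,
    )
    burst = env * np.sin(2 * np.pi * tone.carrier_hz * t)
    for ev in events:
        k = int(round(ev * fs))
        seg = burst[: max(0, min(n_tone, n_total - k))]
        out[k : k + seg.size] += seg
    m = np.max(np.abs(out))
    if m > 0:
        out *= peak / m
    return out


def acoustic_rsm(conditions: list[RhythmCondition]) -> RSM:
    """Stimulus similarity: ``1 - |r_i - r_j|`` for every pair of conditions."""
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    r = np.array([c.r for c in conditions])
    matrix = 1.0 - np.abs(r[:, None] - r[None, :])
    return RSM(matrix, kind="one-minus-absdiff", labels=[c.index for c in conditions])


def categorical_model_set(
    n_conditions: int = 13, min_span: int = 2
) -> list[CategoricalModelRSM]:
    """All admissible two-category models: one per boundary position whose
    categories both span at least ``min_span`` conditions."""
    if n_conditions < 2 * min_span:
        raise ValueError(
            f"n_conditions={n_conditions} < 2*min_span={2 * min_span}: no admissible model"
        )
    return [
        CategoricalModelRSM(boundary_after=b, n_conditions=n_conditions)
        for b in range(min_span, n_conditions - min_span + 1)
    ]


def boundary_ratio(
    model: CategoricalModelRSM, conditions: list[RhythmCondition]
) -> float:
    """Boundary position on the ratio scale: midpoint between the last
    first-category ratio and the first second-category ratio."""
    b = model.boundary_after
    if not 1 <= b < len(conditions):
        raise ValueError(f"boundary_after={b} invalid for {len(conditions)} conditions")
    return 0.5 * (conditions[b - 1].r + conditions[b].r)


def design_to_json(
    conditions: list[RhythmCondition], n_cycles: int, path=None
) -> str:
    """Serialize the condition design (indices, ratios, pattern, cycles)."""
    doc = {
        "pattern_s": conditions[0].pattern_s,
        "n_cycles": n_cycles,
        "conditions": [{"index": c.index, "r": c.r} for c in conditions],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def design_from_json(source) -> tuple[list[RhythmCondition], int]:
    """Inverse of :func:`design_to_json`; ``source`` is a path or JSON text."""
    try:
        doc = json.loads(source)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            doc = json.load(fh)
    conditions = [
        RhythmCondition(index=c["index"], r=c["r"], pattern_s=doc["pattern_s"])
        for c in doc["conditions"]
    ]
    return conditions, int(doc["n_cycles"])
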