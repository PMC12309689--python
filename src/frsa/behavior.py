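"""Tapping pipeline: tap cleaning, asynchrony correction, inter-tap-interval
ratios, sigmoid/linear response-curve comparison, and the uniformity test.

Participants tap along with a looping two-interval rhythm.  For each
pattern repetition the two produced inter-tap intervals give a ratio
ITI1/(ITI1+ITI2), the behavioral analog of the stimulus ratio.  Produced
ratios that cluster at category attractors rather than tracking the
stimulus continuum are the behavioral signature of rhythm categorization:
a sigmoid (not a line) relating produced to stimulus ratios, and a
non-uniform pooled ratio distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TapTrial",
    "ITIResult",
    "CurveFit",
    "clean_extra_taps",
    "asynchrony_correct",
    "mean_asynchrony",
    "iti_ratios",
    "fit_sigmoid",
    "fit_response_curves",
    "chi2_uniformity",
]


@dataclass
class TapTrial:
    """Tap-onset timestamps for one trial of one condition."""

    onsets_s: np.ndarray
    condition: object = None  # RhythmCondition
    trial: int = 0
    force: object = None  # optional ContinuousRecording

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("tap onsets must be strictly increasing")


@dataclass
class ITIResult:
    """Per-cycle produced interval ratios; NaN marks excluded cycles."""

    per_cycle_ratios: np.ndarray
    excluded_reason: list = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.per_cycle_ratios)))

    @property
    def mean_ratio(self) -> float:
        valid = self.per_cycle_ratios[np.isfinite(self.per_cycle_ratios)]
        return float(valid.mean()) if valid.size else float("nan")


@dataclass
class CurveFit:
    """A fitted response curve (sigmoid or linear) with in-sample and
    cross-validated goodness of fit."""

    kind: str
    params: dict
    r2: float
    cv_r2: np.ndarray | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.kind == "sigmoid":
            return _logistic4(x, p["a"], p["b"], p["x0"], p["k"])
        return p["intercept"] + p["slope"] * x


def clean_extra_taps(onsets_s, min_gap_s: float = 0.030) -> np.ndarray:
    """Drop accidental double-contacts: scanning left to right, any onset
    closer than ``min_gap_s`` to the previously *retained* onset is
    removed (greedy, so chains collapse onto the first tap)."""
    onsets = np.asarray(onsets_s, dtype=float)
    kept: list[float] = []
    for t in onsets:
        if not kept or t - kept[-1] >= min_gap_s:
            kept.append(t)
    return np.asarray(kept)


def mean_asynchrony(onsets_s, tone_times_s) -> float:
    """Mean (tap - nearest tone) asynchrony; typically negative because
    people tap slightly ahead of the pacing tone.  Pool onsets/tones over
    all of a participant's trials before calling for the participant-wide
    constant."""
    onsets = np.asarray(onsets_s, dtype=float)
    tones = np.asarray(tone_times_s, dtype=float)
    if onsets.size == 0 or tones.size == 0:
        raise ValueError("need >= 1 tap and >= 1 tone")
    nearest = tones[np.argmin(np.abs(onsets[:, None] - tones[None, :]), axis=1)]
    return float(np.mean(onsets - nearest))


def asynchrony_correct(
    onsets_s,
    tone_times_s,
    max_resid_s: float = 0.080,
    mean_asynchrony_s: float | None = None,
):
    """Subtract the mean tap-tone asynchrony, then flag residual outliers.

    ``mean_asynchrony_s`` should be the participant-wide constant pooled
    over trials and conditions; if None it is computed from this trial
    alone.  Taps whose residual |tap - nearest tone| exceeds
    ``max_resid_s`` after correction are flagged excluded (attentional
    lapses / motor errors).

    Returns ``(corrected_onsets, excluded_flags, mean_asynchrony_s)``.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    tones = np.asarray(tone_times_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("no taps to correct")
    if mean_asynchrony_s is None:
        mean_asynchrony_s = mean_asynchrony(onsets, tones)
    corrected = onsets - mean_asynchrony_s
    nearest = tones[np.argmin(np.abs(corrected[:, None] - tones[None, :]), axis=1)]
    excluded = np.abs(corrected - nearest) > max_resid_s
    return corrected, excluded, float(mean_asynchrony_s)


def _match_tones_to_taps(tone_times: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Nearest-tap index per tone, with exclusive assignment: when one tap
    is nearest to several tones the pairing with the smaller |asynchrony|
    wins and the losing tones stay unmatched (-1)."""
    if taps.size == 0:
        return np.full(tone_times.size, -1, dtype=int)
    nearest = np.argmin(np.abs(tone_times[:, None] - taps[None, :]), axis=1)
    dist = np.abs(tone_times - taps[nearest])
    match = np.full(tone_times.size, -1, dtype=int)
    for tap_idx in np.unique(nearest):
        contenders = np.flatnonzero(nearest == tap_idx)
        winner = contenders[np.argmin(dist[contenders])]
        match[winner] = tap_idx
    return match


def iti_ratios(corrected_onsets_s, sequence) -> ITIResult:
    """Per-cycle produced interval ratios from asynchrony-corrected taps.

    For cycle k the two tones of the cycle and the first tone of cycle
    k+1 are each matched with their exclusive-closest tap; then
    ITI1 = tap2-tap1, ITI2 = tap3-tap2, ratio = ITI1/(ITI1+ITI2).  A
    cycle with any unmatched tone is excluded (NaN), neighbors unaffected.
    """
    taps = np.asarray(corrected_onsets_s, dtype=float)
    tones = sequence.tone_times(include_final=True)
    match = _match_tones_to_taps(tones, taps)
    n_cycles = sequence.n_cycles
    ratios = np.full(n_cycles, np.nan)
    reasons: list = [None] * n_cycles
    for k in range(n_cycles):
        i1, i2, i3 = 2 * k, 2 * k + 1, 2 * k + 2
        if match[i1] < 0 or match[i2] < 0 or match[i3] < 0:
            reasons[k] = "unmatched tone"
            continue
        t1, t2, t3 = taps[match[i1]], taps[match[i2]], taps[match[i3]]
        iti1, iti2 = t2 - t1, t3 - t2
        total = iti1 + iti2
        if iti1 <= 0 or iti2 <= 0:
            reasons[k] = "non-positive interval"
            continue
        ratios[k] = iti1 / total
    return ITIResult(per_cycle_ratios=ratios, excluded_reason=reasons)


def _logistic4(x, a, b, x0, k):
    return a + (b - a) / (1.0 + np.exp(-k * (x - x0)))


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_sigmoid(x, y) -> CurveFit:
    """Least-squares 4-parameter logistic y = a + (b-a)/(1+exp(-k(x-x0)))
    with free asymptotes; threshold = inflection x0.  Five deterministic
    starting points guard against local minima."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    starts = [
        (y_lo, y_hi, lo + f * span, k0)
        for f, k0 in ((0.5, 50.0), (0.35, 50.0), (0.65, 50.0), (0.5, 10.0), (0.5, 200.0))
    ]
    bounds = (
        [-np.inf, -np.inf, lo, 1e-6],
        [np.inf, np.inf, hi, np.inf],
    )
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _logistic4, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _logistic4(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("sigmoid fit failed from all 5 deterministic starts")
    a, b, x0, k = best[1]
    params = {"a": float(a), "b": float(b), "x0": float(x0), "k": float(k)}
    return CurveFit(kind="sigmoid", params=params, r2=_r2(y, _logistic4(x, a, b, x0, k)))


def _fit_linear(x, y) -> CurveFit:
    slope, intercept = np.polyfit(x, y, 1)
    params = {"slope": float(slope), "intercept": float(intercept)}
    fit = CurveFit(kind="linear", params=params, r2=0.0)
    fit.r2 = _r2(y, fit.predict(x))
    return fit


def fit_response_curves(x, y, groups):
    """Sigmoid vs linear description of produced-vs-stimulus ratios.

    ``x``/``y`` are pooled per-participant-per-condition points and
    ``groups`` the participant id of each point.  Both models are fitted
    by least squares on the pooled data, evaluated by
    leave-one-participant-out cross-validation (held-out R^2 per fold),
    and the two sets of per-fold R^2 are compared with a Wilcoxon rank-sum
    test.  Returns ``(sigmoid_fit, linear_fit, p_comparison)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    participants = np.unique(groups)
    if participants.size < 3:
        raise ValueError("need >= 3 participants for leave-one-out comparison")
    sig = fit_sigmoid(x, y)
    lin = _fit_linear(x, y)
    cv_sig, cv_lin = [], []
    for p in participants:
        train, test = groups != p, groups == p
        s = fit_sigmoid(x[train], y[train])
        l = _fit_linear(x[train], y[train])
        cv_sig.append(_r2(y[test], s.predict(x[test])))
        cv_lin.append(_r2(y[test], l.predict(x[test])))
    sig.cv_r2 = np.asarray(cv_sig)
    lin.cv_r2 = np.asarray(cv_lin)
    p_cmp = float(stats.ranksums(sig.cv_r2, lin.cv_r2).pvalue)
    return sig, lin, p_cmp


def chi2_uniformity(ratios, n_bins: int = 13, range=None):
    """Chi-squared goodness of fit of pooled produced ratios against a
    uniform distribution over ``n_bins`` equal bins spanning ``range``
    (default: the observed stimulus-ratio range).  Values outside the
    range count toward the nearest edge bin.  Returns (chi2, df, p)."""
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no ratios to test")
    if range is None:
        range = (float(r.min()), float(r.max()))
    lo, hi = range
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(r, lo, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    res = stats.chisquare(counts)
    return float(res.statistic), n_bins - 1, float(res.pvalue)
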