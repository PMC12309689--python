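"""Prototype-similarity analysis.

Which two-interval rhythm does a response actually resemble?  A dense
grid of noiseless two-impulse-per-cycle templates spanning interval
ratios 0.50-0.84 is rendered, and each template's magnitude fingerprint
at the frequencies of interest is correlated with bootstrap-averaged,
noise-corrected response magnitudes.  The ratio of the maximally
correlated template, accumulated over bootstrap resamples of
participants, forms a distribution per condition whose concentration
(on or off the stimulus ratio) and pooled density peaks reveal the
attractor ratios underlying each category.

A two-impulse cycle at ratio r has Fourier magnitude proportional to
``2|cos(pi k r)|`` at harmonic k — the closed form used as the oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .spectral import FrequencySet, fft_spectrum, harmonic_frequencies

__all__ = [
    "PrototypeSet",
    "PrototypeDistribution",
    "WindowTestResult",
    "PeakResult",
    "build_prototype_set",
    "bootstrap_best_prototype",
    "on_stimulus_test",
    "pooled_peaks",
    "PrototypeSimilarity",
    "PrototypeSimilarityResults",
]


@dataclass
class PrototypeSet:
    """Grid of two-interval impulse-train templates and their magnitude
    fingerprints at the frequencies of interest."""

    ratios: np.ndarray          # nominal template ratios, strictly increasing
    effective_ratios: np.ndarray  # impulse-sample offset / pattern samples
    magnitude_vectors: np.ndarray  # (n_templates, n_foi)
    fois: FrequencySet
    pattern_s: float
    fs: float

    @property
    def n(self) -> int:
        return self.ratios.size

    @property
    def range(self) -> tuple[float, float]:
        return float(self.ratios[0]), float(self.ratios[-1])

    @property
    def span(self) -> float:
        return float(self.ratios[-1] - self.ratios[0])


@dataclass
class PrototypeDistribution:
    """Best-matching template ratio per bootstrap iteration, per condition."""

    per_condition: np.ndarray  # (n_conditions, n_boot) ratios; NaN = undefined
    n_boot: int
    seed: object = None
    n_undefined: int = 0


@dataclass
class WindowTestResult:
    """On-stimulus window test for one condition."""

    center: float
    in_width: float
    out_width: float
    index_samples: np.ndarray
    p: float
    p_bonf: float
    off_stimulus: bool


@dataclass
class PeakResult:
    """A pooled-density peak and its flank-contrast significance."""

    category: int
    peak_ratio: float
    p: float
    p_bonf: float
    bandwidth: float
    index_samples: np.ndarray = field(repr=False, default=None)


def build_prototype_set(
    n: int = 76,
    r_min: float = 0.50,
    r_max: float = 0.84,
    pattern_s: float = 0.75,
    n_cycles: int = 30,
    fs: float = 256.0,
    fois: FrequencySet | None = None,
    f_max_hz: float = 16.0,
) -> PrototypeSet:
    """Render ``n`` equally spaced two-impulse templates and take their
    magnitude fingerprints at the FOIs.

    Each template is 22.5 s of two unit impulses per 750-ms cycle, at the
    cycle start and at ``r * pattern_s`` (rounded to the sample grid;
    ``effective_ratios`` records the rounded value).  A ratio whose two
    impulses collide on one sample at ``fs`` is rejected.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    ratios = np.linspace(r_min, r_max, n)
    pat = int(round(pattern_s * fs))
    n_samples = pat * n_cycles
    if fois is None:
        fois = harmonic_frequencies(pattern_s, f_max_hz, fs / n_samples)
    offsets = np.round(ratios * pat).astype(int)
    if np.any((offsets <= 0) | (offsets >= pat)):
        bad = ratios[(offsets <= 0) | (offsets >= pat)]
        raise ValueError(f"impulse collision at fs={fs} for ratios {bad[:5]}")
    mags = np.empty((n, fois.n))
    for i, off in enumerate(offsets):
        x = np.zeros(n_samples)
        starts = np.arange(n_cycles) * pat
        x[starts] = 1.0
        x[starts + off] = 1.0
        spec = fft_spectrum(x, fs)
        mags[i] = spec.magnitudes[0, fois.bin_indices]
    return PrototypeSet(
        ratios=ratios,
        effective_ratios=offsets / pat,
        magnitude_vectors=mags,
        fois=fois,
        pattern_s=pattern_s,
        fs=fs,
    )


def _std_rows(a: np.ndarray) -> np.ndarray:
    """Center and unit-norm along the last axis; zero-variance rows -> 0."""
    z = a - a.mean(axis=-1, keepdims=True)
    nrm = np.linalg.norm(z, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        z = np.where(nrm > 0, z / np.where(nrm == 0, 1.0, nrm), 0.0)
    return z


def _bootstrap_argmax(
    magnitudes: np.ndarray, pset: PrototypeSet, n_iter: int, rng, chunk: int = 2000
):
    """Core resampling loop, vectorized.

    ``magnitudes``: (n_participants, n_conditions, n_foi) noise-corrected
    magnitude vectors.  Per iteration: resample participants with
    replacement, average their (linearly noise-corrected) magnitude
    vectors, Pearson-correlate with every template fingerprint, record
    the argmax template per condition.  Returns ``(ratios, n_undefined)``
    with ratios of shape (n_conditions, n_iter).
    """
    mag = np.asarray(magnitudes, dtype=float)
    P, C, F = mag.shape
    T = _std_rows(pset.magnitude_vectors)  # (n_templates, F)
    out = np.empty((C, n_iter))
    n_undef = 0
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        draws = rng.integers(0, P, size=(b, P))
        avg = mag[draws].mean(axis=1)  # (b, C, F)
        z = _std_rows(avg)
        flat = np.all(z == 0, axis=-1)  # (b, C)
        corr = z @ T.T  # (b, C, n_templates)
        best = corr.argmax(axis=-1)
        vals = pset.ratios[best].T  # (C, b)
        vals[flat.T] = np.nan
        n_undef += int(flat.sum())
        out[:, done : done + b] = vals
        done += b
    return out, n_undef


def bootstrap_best_prototype(
    magnitudes, pset: PrototypeSet, n_boot: int = 1000, seed=None
) -> PrototypeDistribution:
    """Distribution of maximally correlated template ratios per condition
    over ``n_boot`` participant resamples (see :func:`_bootstrap_argmax`).

    Because the local-noise correction is linear in the magnitude
    spectrum, averaging per-participant noise-corrected vectors equals
    noise-correcting the averaged spectrum.
    """
    mag = np.asarray(magnitudes, dtype=float)
    if mag.ndim != 3:
        raise ValueError("magnitudes must be (participants, conditions, fois)")
    if mag.shape[0] < 1:
        raise ValueError("need >= 1 participant")
    rng = np.random.default_rng(seed)
    vals, n_undef = _bootstrap_argmax(mag, pset, n_boot, rng)
    return PrototypeDistribution(
        per_condition=vals, n_boot=n_boot, seed=seed, n_undefined=n_undef
    )


def _stimulus_window(condition_index: int, grid) -> tuple[float, float]:
    """Window delimited by midpoints to the neighboring conditions; edge
    conditions get the symmetric half-step."""
    r = np.array([c.r for c in grid])
    i = condition_index - 1
    step_lo = (r[i] - r[i - 1]) / 2 if i > 0 else (r[i + 1] - r[i]) / 2
    step_hi = (r[i + 1] - r[i]) / 2 if i < r.size - 1 else (r[i] - r[i - 1]) / 2
    return float(r[i] - step_lo), float(r[i] + step_hi)


def _window_index(samples: np.ndarray, lo, hi, total_span, out_count=None):
    """Density-contrast index: n_in/width_in - n_out/width_out."""
    s = samples[np.isfinite(samples)]
    n_in = int(np.sum((s >= lo) & (s <= hi)))
    n_out = s.size - n_in if out_count is None else out_count
    w_in = hi - lo
    w_out = total_span - w_in
    return n_in / w_in - n_out / w_out


def on_stimulus_test(
    magnitudes,
    pset: PrototypeSet,
    condition_index: int,
    grid,
    n_boot: int = 1000,
    n_outer: int = 500,
    seed=None,
    n_conditions_bonf: int | None = None,
) -> WindowTestResult:
    """Is the best-prototype distribution concentrated on the stimulus?

    The in-window spans the midpoints to the neighboring conditions on
    the continuum; the out-region is the rest of the template range.  The
    in-out index ``n_in/width_in - n_out/width_out`` is recomputed over
    ``n_outer`` full re-runs of the ``n_boot``-iteration bootstrap.  The
    condition is flagged off-stimulus when the index is negative in more
    than 95% of runs after Bonferroni correction over the conditions:
    p = add-one proportion of runs with index >= 0, p_bonf = p x 13.
    """
    rng = np.random.default_rng(seed)
    lo, hi = _stimulus_window(condition_index, grid)
    m = n_conditions_bonf if n_conditions_bonf is not None else len(grid)
    idx = np.empty(n_outer)
    ci = condition_index - 1
    mag = np.asarray(magnitudes, dtype=float)[:, [ci], :]
    for k in range(n_outer):
        vals, _ = _bootstrap_argmax(mag, pset, n_boot, rng)
        idx[k] = _window_index(vals[0], lo, hi, pset.span)
    p = float((np.sum(idx >= 0) + 1) / (n_outer + 1))
    p_bonf = min(1.0, p * m)
    return WindowTestResult(
        center=grid[ci].r,
        in_width=hi - lo,
        out_width=pset.span - (hi - lo),
        index_samples=idx,
        p=p,
        p_bonf=p_bonf,
        off_stimulus=p_bonf < 0.05,
    )


def _find_peaks_kde(samples: np.ndarray, pset: PrototypeSet, n_grid: int = 512):
    """Gaussian KDE (Silverman bandwidth) over the template range; peaks
    are local maxima with density above 10% of the mean grid density."""
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(*pset.range, n_grid)
    dens = kde(grid)
    locs, _ = sps.find_peaks(dens, height=0.1 * dens.mean())
    bw = float(kde.factor * samples.std(ddof=1))
    return grid[locs], bw


def pooled_peaks(
    magnitudes,
    pset: PrototypeSet,
    category_split: int,
    grid_spacing: float,
    n_boot: int = 1000,
    n_outer: int = 500,
    seed=None,
) -> list[PeakResult]:
    """Attractor ratios per category.

    Best-template ratios are pooled over the conditions of each category
    (split after condition ``category_split``), peaks located on the
    pooled KDE, and each peak tested by contrasting counts in a window of
    width ``grid_spacing`` centered on it against its two flanks of half
    that width, over ``n_outer`` re-runs of the bootstrap.  p = add-one
    proportion of runs with index <= 0 (a true peak concentrates samples
    in the window), Bonferroni corrected by the number of peaks tested.
    """
    rng = np.random.default_rng(seed)
    mag = np.asarray(magnitudes, dtype=float)
    n_cond = mag.shape[1]
    if not 1 <= category_split < n_cond:
        raise ValueError(f"category_split={category_split} leaves an empty category")
    cats = {1: np.arange(category_split), 2: np.arange(category_split, n_cond)}

    main, _ = _bootstrap_argmax(mag, pset, n_boot, rng)
    peaks: list[tuple[int, float, float]] = []
    for cat, cols in cats.items():
        pooled = main[cols].ravel()
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size < 2:
            continue
        if np.unique(pooled).size < 2:
            # delta distribution: the unique template is the peak itself
            peaks.append((cat, float(pooled[0]), 0.0))
            continue
        locs, bw = _find_peaks_kde(pooled, pset)
        peaks.extend((cat, float(r), bw) for r in locs)
    if not peaks:
        return []

    idx_samples = np.zeros((len(peaks), n_outer))
    for k in range(n_outer):
        vals, _ = _bootstrap_argmax(mag, pset, n_boot, rng)
        for j, (cat, r0, _) in enumerate(peaks):
            pooled = vals[cats[cat]].ravel()
            pooled = pooled[np.isfinite(pooled)]
            half_w, half_f = grid_spacing / 2, grid_spacing / 4
            n_in = np.sum((pooled >= r0 - half_w) & (pooled <= r0 + half_w))
            n_fl = np.sum(
                ((pooled >= r0 - half_w - half_f) & (pooled < r0 - half_w))
                | ((pooled > r0 + half_w) & (pooled <= r0 + half_w + half_f))
            )
            idx_samples[j, k] = n_in / grid_spacing - n_fl / grid_spacing
    results = []
    for j, (cat, r0, bw) in enumerate(peaks):
        p = float((np.sum(idx_samples[j] <= 0) + 1) / (n_outer + 1))
        results.append(
            PeakResult(
                category=cat,
                peak_ratio=r0,
                p=p,
                p_bonf=min(1.0, p * len(peaks)),
                bandwidth=bw,
                index_samples=idx_samples[j],
            )
        )
    return results


class PrototypeSimilarity:
    """Prototype-similarity model of per-participant response magnitudes.

    Parameters
    ----------
    magnitudes : (n_participants, n_conditions, n_foi) array
        Noise-corrected magnitude vectors (see
        :func:`frsa.spectral.noise_corrected_magnitudes`).
    prototype_set : PrototypeSet
    conditions : sequence of RhythmCondition
        The stimulus continuum the responses were recorded under.
    """

    def __init__(self, magnitudes, prototype_set: PrototypeSet, conditions):
        self.magnitudes = np.asarray(magnitudes, dtype=float)
        self.prototype_set = prototype_set
        self.conditions = list(conditions)
        if self.magnitudes.ndim != 3:
            raise ValueError("magnitudes must be (participants, conditions, fois)")
        if self.magnitudes.shape[1] != len(self.conditions):
            raise ValueError("condition count mismatch")
        if self.magnitudes.shape[2] != prototype_set.fois.n:
            raise ValueError("FOI count mismatch with the prototype set")

    def fit(
        self,
        category_split: int | None = None,
        n_boot: int = 1000,
        n_outer: int = 500,
        seed=None,
    ) -> "PrototypeSimilarityResults":
        rng = np.random.default_rng(seed)
        dist = bootstrap_best_prototype(
            self.magnitudes, self.prototype_set, n_boot=n_boot,
            seed=rng.integers(2**31),
        )
        window_tests = [
            on_stimulus_test(
                self.magnitudes,
                self.prototype_set,
                c.index,
                self.conditions,
                n_boot=n_boot,
                n_outer=n_outer,
                seed=rng.integers(2**31),
            )
            for c in self.conditions
        ]
        peaks = None
        if category_split is not None:
            spacing = self.conditions[1].r - self.conditions[0].r
            peaks = pooled_peaks(
                self.magnitudes,
                self.prototype_set,
                category_split,
                spacing,
                n_boot=n_boot,
                n_outer=n_outer,
                seed=rng.integers(2**31),
            )
        return PrototypeSimilarityResults(
            model=self, distribution=dist, window_tests=window_tests, peaks=peaks
        )


@dataclass
class PrototypeSimilarityResults:
    model: PrototypeSimilarity
    distribution: PrototypeDistribution
    window_tests: list
    peaks: list | None = None

    def summary(self) -> str:
        lines = [
            "Prototype-similarity analysis",
            "=" * 60,
            f"{'cond':>5} {'stim r':>8} {'mode r':>8} {'p_bonf':>9} {'off?':>6}",
        ]
        for c, wt in zip(self.model.conditions, self.window_tests):
            row = self.distribution.per_condition[c.index - 1]
            row = row[np.isfinite(row)]
            mode = stats.mode(row, keepdims=False).mode if row.size else np.nan
            lines.append(
                f"{c.index:>5} {c.r:>8.3f} {mode:>8.3f} {wt.p_bonf:>9.3g} "
                f"{'yes' if wt.off_stimulus else 'no':>6}"
            )
        if self.peaks is not None:
            lines.append("-" * 60)
            lines.append("pooled density peaks:")
            for pk in self.peaks:
                lines.append(
                    f"  category {pk.category}: ratio {pk.peak_ratio:.3f} "
                    f"(p_bonf = {pk.p_bonf:.3g}, bw = {pk.bandwidth:.4f})"
                )
        return "\n".join(lines)

    def distribution_frame(self):
        """(condition, iteration, best_ratio) long-format table."""
        import pandas as pd

        C, B = self.distribution.per_condition.shape
        return pd.DataFrame(
            {
                "condition": np.repeat(np.arange(1, C + 1), B),
                "iteration": np.tile(np.arange(B), C),
                "best_ratio": self.distribution.per_condition.ravel(),
            }
        )
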