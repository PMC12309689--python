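"""End-to-end workflows: from tap logs (or simulation) to fitted fRSA.

Per participant the tapping data feed two parallel routes:

* the ITI route — clean taps, subtract the participant's mean
  asynchrony, extract per-cycle produced interval ratios, average per
  condition, and build a ``1 - |diff|`` RSM from the means;
* the fRSA route — raw tap onsets become unit impulse trains, averaged
  across trials in the time domain, Fourier transformed, and the re/im
  coefficients at the harmonics of the pattern rate become feature
  vectors for a correlation RSM.

Both RSM sets are fitted with :class:`~frsa.inference.CategoricalRSA`;
noise-corrected magnitude vectors additionally feed the prototype
analysis.  :func:`run_pipeline` drives everything from a config mapping
(or YAML path) and writes JSON/CSV results plus a Markdown report.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, design, inference, prototypes, rsm, signal, spectral
from .synthetic import SimulationSpec, simulate_tap_participant

__all__ = [
    "participant_iti_means",
    "tap_condition_spectrum",
    "participant_tap_features",
    "run_pipeline",
]


def participant_iti_means(trials, conditions, n_cycles: int = 30):
    """Mean produced ITI ratio per condition for one participant.

    Applies the full cleaning chain: 30-ms double-contact removal, the
    participant-wide mean-asynchrony correction (pooled over all trials
    and conditions), 80-ms residual exclusion, exclusive nearest-tap
    matching per tone.  Returns ``(means, n_valid)`` arrays over
    conditions (NaN where no cycle survived).
    """
    sequences = {c.index: design.build_sequence(c, n_cycles) for c in conditions}
    cleaned = [
        (t, behavior.clean_extra_taps(t.onsets_s))
        for t in trials
        if t.onsets_s.size
    ]
    all_async = [
        behavior.mean_asynchrony(taps, sequences[t.condition.index].tone_times())
        * taps.size
        for t, taps in cleaned
    ]
    n_taps = sum(taps.size for _, taps in cleaned)
    if n_taps == 0:
        raise ValueError("participant has no taps")
    pooled_mean = float(np.sum(all_async) / n_taps)

    by_cond: dict[int, list[float]] = {c.index: [] for c in conditions}
    for t, taps in cleaned:
        seq = sequences[t.condition.index]
        corrected, excluded, _ = behavior.asynchrony_correct(
            taps, seq.tone_times(), mean_asynchrony_s=pooled_mean
        )
        corrected = corrected[~excluded]
        if corrected.size == 0:
            continue
        res = behavior.iti_ratios(corrected, seq)
        by_cond[t.condition.index].extend(
            res.per_cycle_ratios[np.isfinite(res.per_cycle_ratios)]
        )
    means = np.array(
        [np.mean(by_cond[c.index]) if by_cond[c.index] else np.nan for c in conditions]
    )
    n_valid = np.array([len(by_cond[c.index]) for c in conditions])
    return means, n_valid


def tap_condition_spectrum(tap_trials, duration_s: float, fs: float = 256.0):
    """Average the per-trial impulse trains in the time domain and take
    the FFT — the tap-onset response spectrum for one condition."""
    trains = [
        signal.impulse_train(t.onsets_s, fs, duration_s).samples[0]
        for t in tap_trials
    ]
    return spectral.fft_spectrum(np.mean(trains, axis=0), fs)


def participant_tap_features(
    trials, conditions, n_cycles: int = 30, fs: float = 256.0, f_max_hz: float = 16.0
):
    """fRSA features for one participant's tapping.

    Returns ``(feature_rsm, magnitudes)``: the tap-onset correlation RSM
    from re/im coefficients at the FOIs, and the (n_conditions, n_foi)
    noise-corrected magnitude vectors for the prototype analysis.
    """
    pattern_s = conditions[0].pattern_s
    duration = n_cycles * pattern_s
    by_cond: dict[int, list] = {c.index: [] for c in conditions}
    for t in trials:
        by_cond[t.condition.index].append(t)
    feats, mags = [], []
    fois = None
    for c in conditions:
        spec = tap_condition_spectrum(by_cond[c.index], duration, fs)
        if fois is None:
            fois = spectral.harmonic_frequencies(pattern_s, f_max_hz, spec.df_hz)
        feats.append(spectral.feature_vector(spec, fois))
        mags.append(spectral.noise_corrected_magnitudes(spec.magnitudes[0], fois))
    labels = [c.index for c in conditions]
    return rsm.rsm_from_features(feats, labels=labels), np.asarray(mags)


DEFAULT_CONFIG = {
    "simulate": {"n_participants": 18, "seed": 0},
    "analysis": {
        "f_max_tap_hz": 16.0,
        "fs": 256.0,
        "n_perm_individual": 5000,
        "n_perm_group": 10000,
        "n_boot_boundary": 10000,
        "n_boot_prototype": 1000,
        "n_outer_prototype": 500,
        "run_prototypes": False,
        "seed": 0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def run_pipeline(config=None, out_dir=None) -> dict:
    """Run the tapping pipeline end to end and return the results bundle.

    ``config`` is a mapping (or YAML path) overriding
    :data:`DEFAULT_CONFIG`; supply ``config["dataset"]`` (a directory
    with ``design.json`` + ``taps.csv``) to analyze recorded data, else a
    dataset is simulated from ``config["simulate"]``.  When ``out_dir``
    is given, JSON/CSV results and a Markdown report are written there.
    Every stochastic step draws its seed from ``analysis.seed``; the
    returned bundle embeds the config hash and library versions.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(DEFAULT_CONFIG, config or {})
    ana = cfg["analysis"]
    rng = np.random.default_rng(ana["seed"])

    if cfg.get("dataset"):
        from .io import read_tap_log

        root = Path(cfg["dataset"])
        conditions, n_cycles = design.design_from_json(root / "design.json")
        taps_by_participant = read_tap_log(root / "taps.csv", conditions)
    else:
        sim = dict(cfg["simulate"])
        n_participants = sim.pop("n_participants", 18)
        spec = SimulationSpec(**sim)
        conditions, n_cycles = spec.design, spec.n_cycles
        taps_by_participant = {
            pid: simulate_tap_participant(spec, pid) for pid in range(n_participants)
        }

    acoustic = design.acoustic_rsm(conditions)
    models = design.categorical_model_set(len(conditions))

    # per-participant features
    iti_means, onset_rsms, magnitudes = [], [], []
    for pid in sorted(taps_by_participant):
        trials = taps_by_participant[pid]
        means, _ = participant_iti_means(trials, conditions, n_cycles)
        iti_means.append(means)
        r, m = participant_tap_features(
            trials, conditions, n_cycles, ana["fs"], ana["f_max_tap_hz"]
        )
        onset_rsms.append(r)
        magnitudes.append(m)
    iti_means = np.asarray(iti_means)
    iti_rsms = [rsm.rsm_from_scalars(row) for row in iti_means]

    # categorical fRSA fits
    fit_kwargs = dict(
        n_perm_individual=ana["n_perm_individual"],
        n_perm_group=ana["n_perm_group"],
        n_boot=ana["n_boot_boundary"],
    )
    iti_fit = inference.CategoricalRSA(
        iti_rsms, acoustic, models, conditions
    ).fit(seed=rng.integers(2**31), **fit_kwargs)
    onset_fit = inference.CategoricalRSA(
        onset_rsms, acoustic, models, conditions
    ).fit(seed=rng.integers(2**31), **fit_kwargs)

    # behavioral time-domain analyses
    stim_r = np.array([c.r for c in conditions])
    x = np.tile(stim_r, len(iti_means))
    y = iti_means.ravel()
    groups = np.repeat(np.arange(len(iti_means)), len(conditions))
    ok = np.isfinite(y)
    sig, lin, p_cmp = behavior.fit_response_curves(x[ok], y[ok], groups[ok])
    chi2, df_chi, p_chi = behavior.chi2_uniformity(
        y[ok], n_bins=len(conditions), range=(stim_r.min(), stim_r.max())
    )

    results = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_participants": len(taps_by_participant),
        "iti": iti_fit.to_dict(),
        "tap_onset": onset_fit.to_dict(),
        "sigmoid": {
            "params": sig.params,
            "r2": sig.r2,
            "cv_r2": sig.cv_r2.tolist(),
        },
        "linear": {"params": lin.params, "r2": lin.r2, "cv_r2": lin.cv_r2.tolist()},
        "sigmoid_vs_linear_p": p_cmp,
        "chi2_uniformity": {"chi2": chi2, "df": df_chi, "p": p_chi},
    }

    proto_res = None
    if ana["run_prototypes"]:
        pset = prototypes.build_prototype_set(
            pattern_s=conditions[0].pattern_s,
            n_cycles=n_cycles,
            fs=ana["fs"],
            f_max_hz=ana["f_max_tap_hz"],
        )
        split = int(np.median(onset_fit.best_boundaries))
        proto_res = prototypes.PrototypeSimilarity(
            np.asarray(magnitudes), pset, conditions
        ).fit(
            category_split=split,
            n_boot=ana["n_boot_prototype"],
            n_outer=ana["n_outer_prototype"],
            seed=rng.integers(2**31),
        )
        results["prototypes"] = {
            "category_split": split,
            "off_stimulus": [wt.off_stimulus for wt in proto_res.window_tests],
            "window_p_bonf": [wt.p_bonf for wt in proto_res.window_tests],
            "peaks": [
                {"category": pk.category, "ratio": pk.peak_ratio, "p_bonf": pk.p_bonf}
                for pk in (proto_res.peaks or [])
            ],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
        pd.DataFrame(
            iti_means,
            columns=[c.index for c in conditions],
        ).to_csv(out / "iti_means.csv", index_label="participant")
        report = [
            "# fRSA pipeline report",
            f"config hash: `{results['config_hash']}`",
            "",
            "## ITI RSA",
            "```", iti_fit.summary(), "```",
            "",
            "## Tap-onset fRSA",
            "```", onset_fit.summary(), "```",
            "",
            f"sigmoid vs linear (LOPO CV, rank-sum): p = {p_cmp:.4g}",
            f"chi-squared uniformity: chi2({df_chi}) = {chi2:.2f}, p = {p_chi:.3g}",
        ]
        if proto_res is not None:
            report += ["", "## Prototypes", "```", proto_res.summary(), "```"]
        (out / "report.md").write_text("\n".join(report))

    results["_objects"] = {
        "iti_fit": iti_fit,
        "onset_fit": onset_fit,
        "prototypes": proto_res,
        "conditions": conditions,
        "magnitudes": np.asarray(magnitudes),
        "iti_means": iti_means,
    }
    return results
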