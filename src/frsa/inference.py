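"""Statistical evaluation of shared structure in RSMs.

The central question: does a response RSM carry categorical structure
beyond what the stimulus continuum itself induces?  The test statistic is
Spearman's partial correlation between the lower triangles of the
response RSM and each theoretical two-category model, partialing out the
acoustic RSM; the best-fitting model is the one with the highest
coefficient.  Significance comes from permutation tests that shuffle the
response triangle entries (individual: 5000 iterations; group: 10000),
with Bonferroni correction over the candidate models.  Boundary
consistency across participants is summarized by a bootstrap CI of the
median boundary ratio, and cross-response agreement by Fisher-z model
profiles and t tests.

The statsmodels-style entry point is :class:`CategoricalRSA`; the
functions it wraps are public for piecewise use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rsm import RSM, lower_triangle

__all__ = [
    "ModelFitResult",
    "NullDistribution",
    "spearman_partial",
    "fit_categorical_models",
    "permutation_test_individual",
    "permutation_test_group",
    "bonferroni",
    "bootstrap_median_ci",
    "compare_rsms",
    "compare_rsms_group",
    "model_profile_similarity",
    "t_tests",
    "CategoricalRSA",
    "CategoricalRSAResults",
]


# ---------------------------------------------------------------------------
# partial Spearman correlation

def _ranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, x]."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def spearman_partial(x, y, cov) -> float:
    """Spearman's partial correlation of x and y given cov.

    All three vectors are rank-transformed (average ranks for ties); the
    partial correlation is the Pearson correlation of the residuals of
    the rank vectors after least-squares regression on the covariate
    ranks.  Entries missing (NaN) in any vector are excluded pairwise.
    Zero-variance residuals give NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(cov, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov)
    if keep.sum() < 4:
        raise ValueError("need >= 4 complete observations")
    rx, ry, rc = _ranks(x[keep]), _ranks(y[keep]), _ranks(cov[keep])
    ex, ey = _residualize(rx, rc), _residualize(ry, rc)
    sx, sy = np.sqrt(np.sum(ex**2)), np.sqrt(np.sum(ey**2))
    # residuals that are pure numerical noise (vector rank-identical to the
    # covariate) are undefined, not correlated
    tol = 1e-8 * np.sqrt(len(rx))
    if sx <= tol or sy <= tol:
        return float("nan")
    return float(np.clip(np.dot(ex, ey) / (sx * sy), -1.0, 1.0))


class _PartialCorrEngine:
    """Vectorized partial Spearman of a response triangle against a fixed
    model set given a fixed covariate.

    Because shuffling a vector permutes its ranks, the engine standardizes
    the rank vectors once and computes partial correlations with the
    single-covariate identity
    ``r_xy.c = (r_xy - r_xc r_yc) / sqrt((1-r_xc^2)(1-r_yc^2))``,
    algebraically identical to the residual route of
    :func:`spearman_partial` (asserted in the test suite).
    """

    def __init__(self, model_triangles: np.ndarray, cov_triangle: np.ndarray):
        M = np.atleast_2d(np.asarray(model_triangles, dtype=float))
        c = np.asarray(cov_triangle, dtype=float)
        self.m = c.size
        self.M = np.stack([self._std(_ranks(row)) for row in M], axis=1)  # (m, k)
        self.c = self._std(_ranks(c))
        self.r_mc = self.M.T @ self.c  # (k,)

    @staticmethod
    def _std(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        n = np.sqrt(np.sum(v**2))
        return v / n if n > 0 else v

    def _partial(self, r_xm: np.ndarray, r_xc: np.ndarray) -> np.ndarray:
        denom = np.sqrt(
            np.maximum((1.0 - r_xc**2)[..., None] * (1.0 - self.r_mc**2), 1e-300)
        )
        return np.clip((r_xm - r_xc[..., None] * self.r_mc) / denom, -1.0, 1.0)

    def rho_per_model(self, x_triangle: np.ndarray) -> np.ndarray:
        z = self._std(_ranks(np.asarray(x_triangle, dtype=float)))
        return self._partial(z @ self.M, np.array(z @ self.c))

    def null_max(self, x_triangle: np.ndarray, n_iter: int, rng) -> np.ndarray:
        """Max-over-models partial rho for ``n_iter`` shuffles of the
        response triangle entries."""
        z = self._std(_ranks(np.asarray(x_triangle, dtype=float)))
        perms = rng.permuted(np.tile(z, (n_iter, 1)), axis=1)  # (n_iter, m)
        rho = self._partial(perms @ self.M, perms @ self.c)
        return rho.max(axis=1)


# ---------------------------------------------------------------------------
# model fitting and permutation tests

@dataclass
class ModelFitResult:
    """Partial correlations of one response RSM with the model set."""

    rho_per_model: np.ndarray
    best_model: int  # boundary_after of the winner
    best_rho: float
    p_perm: float | None = None
    p_bonf: float | None = None


@dataclass
class NullDistribution:
    values: np.ndarray
    n_iter: int
    seed: int | None = None


def _triangles(models) -> np.ndarray:
    return np.stack([lower_triangle(m) for m in models])


def _select_best(rho: np.ndarray, models, n_conditions: int) -> int:
    """Argmax with ties broken toward the boundary nearer the continuum
    center (logged), then toward the smaller boundary."""
    best = np.nanmax(rho)
    tied = np.flatnonzero(rho >= best - 1e-12)
    if tied.size > 1:
        center = (n_conditions + 1) / 2.0
        dists = [abs(models[i].boundary_after - center) for i in tied]
        warnings.warn(
            f"{tied.size} models tied at rho={best:.4f}; "
            "breaking toward the central boundary",
            stacklevel=3,
        )
        tied = tied[np.argsort(dists, kind="stable")]
    return int(tied[0])


def fit_categorical_models(response: RSM, models, acoustic: RSM) -> ModelFitResult:
    """Partial Spearman of the response triangle with every categorical
    model, acoustic RSM partialed out; winner = highest coefficient."""
    x = lower_triangle(response)
    cov = lower_triangle(acoustic)
    rho = np.array([spearman_partial(x, lower_triangle(m), cov) for m in models])
    i = _select_best(rho, models, response.n)
    return ModelFitResult(
        rho_per_model=rho, best_model=models[i].boundary_after, best_rho=float(rho[i])
    )


def _p_from_null(null: np.ndarray, observed: float) -> float:
    """Add-one permutation p: (count(null >= observed) + 1)/(n + 1)."""
    return float((np.sum(null >= observed) + 1) / (null.size + 1))


def permutation_test_individual(
    response: RSM, models, acoustic: RSM, n_iter: int = 5000, seed=None
):
    """Permutation test of one participant's best-model fit.

    Each iteration shuffles the lower-triangle entries of the response
    RSM, refits all models, and stores the maximum partial rho; the p
    value is the add-one proportion of null values >= the observed best
    rho.  Returns ``(fit, null)`` with ``fit.p_perm``/``fit.p_bonf`` set.
    """
    rng = np.random.default_rng(seed)
    fit = fit_categorical_models(response, models, acoustic)
    eng = _PartialCorrEngine(_triangles(models), lower_triangle(acoustic))
    null = eng.null_max(lower_triangle(response), n_iter, rng)
    fit.p_perm = _p_from_null(null, fit.best_rho)
    fit.p_bonf = bonferroni(fit.p_perm, len(models))
    return fit, NullDistribution(values=null, n_iter=n_iter, seed=seed)


def permutation_test_group(
    responses, models, acoustic: RSM, n_iter: int = 10000, seed=None
):
    """Group-level permutation test.

    Observed statistic: mean over participants of each one's best-model
    partial rho.  Null: on every iteration each participant's triangle is
    shuffled independently, the best-model rho found per participant, and
    the across-participant mean stored.  Returns
    ``(p, null, observed_mean, fits)``.
    """
    rng = np.random.default_rng(seed)
    fits = [fit_categorical_models(r, models, acoustic) for r in responses]
    observed = float(np.mean([f.best_rho for f in fits]))
    eng = _PartialCorrEngine(_triangles(models), lower_triangle(acoustic))
    acc = np.zeros(n_iter)
    for r in responses:
        acc += eng.null_max(lower_triangle(r), n_iter, rng)
    null = acc / len(responses)
    p = _p_from_null(null, observed)
    return p, NullDistribution(values=null, n_iter=n_iter, seed=seed), observed, fits


def bonferroni(p: float, m: int = 10) -> float:
    """Bonferroni correction: min(1, p * m)."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return min(1.0, p * m)


def bootstrap_median_ci(
    values, n_boot: int = 10000, seed=None, level: float = 0.95
):
    """Percentile CI of the median under resampling of participants with
    replacement.  Returns (median, ci_low, ci_high)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    medians = np.median(v[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(np.median(v)), float(lo), float(hi)


def compare_rsms(a: RSM, b: RSM, acoustic: RSM, n_iter: int = 5000, seed=None):
    """Shared structure between two response RSMs beyond the stimulus:
    partial Spearman given the acoustic RSM, permutation p by shuffling
    one RSM's triangle.  Returns (rho, p)."""
    rng = np.random.default_rng(seed)
    xa, xb, cov = lower_triangle(a), lower_triangle(b), lower_triangle(acoustic)
    rho = spearman_partial(xa, xb, cov)
    eng = _PartialCorrEngine(xb[None, :], cov)
    null = eng.null_max(xa, n_iter, rng)
    return rho, _p_from_null(null, rho)


def compare_rsms_group(
    a_list, b_list, acoustic: RSM, n_iter: int = 10000, seed=None
):
    """Group variant of :func:`compare_rsms`: the statistic is the mean
    over participants of the per-participant partial rho; every
    participant's first-RSM triangle is shuffled independently per
    iteration.  Returns (mean_rho, p, per_participant_rho)."""
    if len(a_list) != len(b_list):
        raise ValueError("participant lists differ in length")
    rng = np.random.default_rng(seed)
    cov = lower_triangle(acoustic)
    rhos, acc = [], np.zeros(n_iter)
    for a, b in zip(a_list, b_list):
        xa, xb = lower_triangle(a), lower_triangle(b)
        rhos.append(spearman_partial(xa, xb, cov))
        eng = _PartialCorrEngine(xb[None, :], cov)
        acc += eng.null_max(xa, n_iter, rng)
    null = acc / len(a_list)
    mean_rho = float(np.mean(rhos))
    return mean_rho, _p_from_null(null, mean_rho), np.asarray(rhos)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    lim = 1.0 - 1e-12
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|rho| == 1 clipped before Fisher transform", stacklevel=3)
    return np.arctanh(np.clip(r, -lim, lim))


def model_profile_similarity(profile_a, profile_b) -> float:
    """Similarity of two model-fit profiles (vectors of partial rhos over
    the candidate boundaries): Fisher-transform each entry, Pearson
    correlate, and return the Fisher z of the resulting r, ready for a
    group one-sample t test against zero."""
    za, zb = _fisher_z(profile_a), _fisher_z(profile_b)
    r = float(np.corrcoef(za, zb)[0, 1])
    return float(_fisher_z(r))


def t_tests(a, b=None):
    """One-sample (against 0) or paired two-sided t test -> (t, df, p).

    A zero-variance, zero-mean difference is reported as (nan, df, 1.0)
    by convention; zero variance with nonzero mean gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if d.size < 2:
        raise ValueError("need n >= 2")
    df = d.size - 1
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            warnings.warn("all differences zero; p = 1 by convention", stacklevel=2)
            return float("nan"), df, 1.0
        return float(np.sign(np.mean(d)) * np.inf), df, 0.0
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# model object

class CategoricalRSA:
    """Categorical-structure model of a set of response RSMs.

    Parameters
    ----------
    responses : RSM or sequence of RSM
        One response RSM per participant (a single RSM is treated as a
        one-participant group).
    acoustic : RSM
        Stimulus similarity matrix, partialed out of every correlation.
    models : sequence of CategoricalModelRSM, optional
        Candidate two-category models; defaults to all admissible
        boundaries for the response dimension (min span 2).
    conditions : sequence of RhythmCondition, optional
        Needed to report boundaries on the ratio scale.

    ``fit()`` runs the individual and group permutation tests and the
    boundary bootstrap and returns a :class:`CategoricalRSAResults`.
    """

    def __init__(self, responses, acoustic, models=None, conditions=None):
        if isinstance(responses, RSM):
            responses = [responses]
        self.responses = list(responses)
        if not self.responses:
            raise ValueError("need >= 1 response RSM")
        self.acoustic = acoustic
        if models is None:
            from .design import categorical_model_set

            models = categorical_model_set(self.responses[0].n, min_span=2)
        self.models = list(models)
        self.conditions = list(conditions) if conditions is not None else None

    def fit(
        self,
        n_perm_individual: int = 5000,
        n_perm_group: int = 10000,
        n_boot: int = 10000,
        seed=None,
    ) -> "CategoricalRSAResults":
        rng = np.random.default_rng(seed)
        fits = []
        for r in self.responses:
            f, _ = permutation_test_individual(
                r,
                self.models,
                self.acoustic,
                n_iter=n_perm_individual,
                seed=rng.integers(2**31),
            )
            fits.append(f)
        group_p, group_null, group_rho, _ = permutation_test_group(
            self.responses,
            self.models,
            self.acoustic,
            n_iter=n_perm_group,
            seed=rng.integers(2**31),
        )
        boundary_ratios = median = ci = None
        if self.conditions is not None:
            from .design import boundary_ratio

            by_id = {m.boundary_after: m for m in self.models}
            boundary_ratios = np.array(
                [boundary_ratio(by_id[f.best_model], self.conditions) for f in fits]
            )
            if len(fits) >= 2:
                median, *ci = bootstrap_median_ci(
                    boundary_ratios, n_boot=n_boot, seed=rng.integers(2**31)
                )
                ci = tuple(ci)
        return CategoricalRSAResults(
            model=self,
            individual_fits=fits,
            group_mean_rho=group_rho,
            group_p=group_p,
            group_p_bonf=bonferroni(group_p, len(self.models)),
            group_null=group_null,
            boundary_ratios=boundary_ratios,
            boundary_median=median,
            boundary_ci=ci,
        )


@dataclass
class CategoricalRSAResults:
    """Estimates, permutation p values and boundary summary for a fitted
    :class:`CategoricalRSA`."""

    model: CategoricalRSA
    individual_fits: list
    group_mean_rho: float
    group_p: float
    group_p_bonf: float
    group_null: NullDistribution
    boundary_ratios: np.ndarray | None = None
    boundary_median: float | None = None
    boundary_ci: tuple | None = None
    bayes_factor: None = field(default=None)  # placeholder; not computed here

    @property
    def best_boundaries(self) -> np.ndarray:
        return np.array([f.best_model for f in self.individual_fits])

    @property
    def individual_p_bonf(self) -> np.ndarray:
        return np.array([f.p_bonf for f in self.individual_fits])

    def profiles(self) -> np.ndarray:
        """(n_participants, n_models) matrix of partial-rho profiles."""
        return np.stack([f.rho_per_model for f in self.individual_fits])

    def summary(self) -> str:
        lines = [
            "Categorical fRSA fit",
            "=" * 60,
            f"participants: {len(self.individual_fits)}   "
            f"models: {len(self.model.models)}",
            f"group mean best-model partial rho: {self.group_mean_rho:.3f}",
            f"group permutation p: {self.group_p:.4g}   "
            f"Bonferroni: {self.group_p_bonf:.4g}",
        ]
        if self.boundary_median is not None:
            lines.append(
                f"median boundary ratio: {self.boundary_median:.3f} "
                f"[95% CI {self.boundary_ci[0]:.3f}, {self.boundary_ci[1]:.3f}]"
            )
        lines.append("-" * 60)
        lines.append(f"{'id':>4} {'best boundary':>14} {'rho':>8} {'p_bonf':>10}")
        for i, f in enumerate(self.individual_fits):
            lines.append(
                f"{i + 1:>4} {f.best_model:>14d} {f.best_rho:>8.3f} "
                f"{f.p_bonf:>10.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "group": {
                "mean_rho": self.group_mean_rho,
                "p": self.group_p,
                "p_bonf": self.group_p_bonf,
                "bayes_factor": None,
            },
            "participants": [
                {
                    "rho_per_model": f.rho_per_model.tolist(),
                    "best_boundary": int(f.best_model),
                    "best_rho": f.best_rho,
                    "p": f.p_perm,
                    "p_bonf": f.p_bonf,
                }
                for f in self.individual_fits
            ],
        }
        if self.boundary_median is not None:
            d["group"]["boundary_median"] = self.boundary_median
            d["group"]["boundary_ci"] = list(self.boundary_ci)
            d["boundary_ratios"] = self.boundary_ratios.tolist()
        return d
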