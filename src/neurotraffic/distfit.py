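"""Maximum-likelihood distribution fits to inter-departure-time samples
and chi-square goodness-of-fit ranking.

The central fit is the two-parameter Gamma density

    f(tau; k, theta) = tau**(k-1) * exp(-tau/theta) / (Gamma(k) * theta**k)

whose coefficient of variation (SD/mean) is k**(-1/2), so the fitted shape
alone determines whether a sample is hypo- (CV < 1) or hyperexponential
(CV > 1).  The Gamma MLE is solved by a safeguarded root-find of the
profile-likelihood (digamma) equation with method-of-moments
initialization.  Competing candidates (Weibull, Exponential, Lognormal,
Normal) are fitted by ML and ranked by ascending chi-square statistic
computed on bins equiprobable under each fitted distribution, with
degrees of freedom reduced by the number of estimated parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .departures import IDTSample

__all__ = [
    "GammaFit",
    "DistFit",
    "GofResult",
    "InsufficientSampleError",
    "DegenerateSampleError",
    "fit_gamma_mle",
    "gamma_cv",
    "fit_weibull_mle",
    "fit_candidates",
    "chi_square_gof",
    "rank_fits",
    "DEFAULT_CANDIDATES",
]

MIN_FIT_SAMPLE = 10


class InsufficientSampleError(ValueError):
    """Sample too small to fit (below the configured minimum)."""


class DegenerateSampleError(ValueError):
    """Zero-variance sample: the shape estimate diverges, no fit exists."""


def _as_intervals(sample) -> np.ndarray:
    x = sample.intervals if isinstance(sample, IDTSample) else np.asarray(sample, float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be 1-D")
    return x


@dataclass(frozen=True)
class DistFit:
    """A fitted candidate distribution.

    ``params`` are the free parameters estimated from the data (their
    count drives the chi-square degree-of-freedom adjustment).
    """

    name: str
    params: tuple[float, ...]
    log_likelihood: float
    n: int
    _frozen: object = None

    @property
    def n_params(self) -> int:
        return len(self.params)

    def pdf(self, x):
        return self._frozen.pdf(x)

    def ppf(self, q):
        return self._frozen.ppf(q)


@dataclass(frozen=True)
class GammaFit(DistFit):
    """Gamma MLE result with shape k, scale theta and CV = k**(-1/2)."""

    @property
    def shape(self) -> float:
        return self.params[0]

    @property
    def scale(self) -> float:
        return self.params[1]

    @property
    def cv(self) -> float:
        return self.shape ** -0.5

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def _check_fit_sample(x: np.ndarray, min_n: int) -> None:
    if x.size < min_n:
        raise InsufficientSampleError(
            f"need >= {min_n} intervals to fit, got {x.size}"
        )
    if np.any(x <= 0):
        raise ValueError("all intervals must be positive")
    if float(x.var()) == 0.0:
        raise DegenerateSampleError(
            "zero-variance sample: shape parameter diverges (no finite MLE)"
        )


def fit_gamma_mle(sample, min_n: int = MIN_FIT_SAMPLE) -> GammaFit:
    """Jointly maximize the Gamma log-likelihood over (shape, scale).

    Profiling out the scale (theta = mean/k) reduces the problem to the
    scalar equation  log(k) - digamma(k) = log(mean) - mean(log x),
    solved by Brent's method on a bracket grown from the
    method-of-moments start; tolerance 1e-10 on k.

    Raises
    ------
    InsufficientSampleError
        Fewer than ``min_n`` intervals.
    DegenerateSampleError
        Zero-variance sample (the likelihood has no finite maximizer).
    """
    x = _as_intervals(sample)
    _check_fit_sample(x, min_n)
    mean = float(x.mean())
    # s > 0 strictly because the sample has positive variance (Jensen).
    s = math.log(mean) - float(np.mean(np.log(x)))

    def g(k: float) -> float:
        return math.log(k) - special.digamma(k) - s

    k0 = max((mean / x.std()) ** 2, 1e-6)  # method-of-moments start
    lo, hi = k0, k0
    while g(lo) < 0:
        lo /= 2.0
    while g(hi) > 0:
        hi *= 2.0
    k_hat = float(optimize.brentq(g, lo, hi, xtol=1e-10, rtol=1e-12))
    theta_hat = mean / k_hat
    frozen = stats.gamma(a=k_hat, scale=theta_hat)
    loglik = float(np.sum(frozen.logpdf(x)))
    return GammaFit("gamma", (k_hat, theta_hat), loglik, x.size, frozen)


def gamma_cv(fit: GammaFit | float) -> float:
    """Coefficient of variation of a Gamma distribution: shape**(-1/2)."""
    shape = fit.shape if isinstance(fit, GammaFit) else float(fit)
    if shape <= 0:
        raise ValueError("shape must be > 0")
    return shape ** -0.5


def _scipy_fit(dist, x: np.ndarray, name: str, fixed: dict) -> DistFit:
    params = dist.fit(x, **fixed)
    frozen = dist(*params)
    loglik = float(np.sum(frozen.logpdf(x)))
    free = [p for i, p in enumerate(params) if _is_free(dist, i, fixed)]
    return DistFit(name, tuple(float(p) for p in free), loglik, x.size, frozen)


def _is_free(dist, i: int, fixed: dict) -> bool:
    shapes = dist.shapes.split(", ") if dist.shapes else []
    names = [f"f{s}" for s in shapes] + ["floc", "fscale"]
    return names[i] not in fixed


def fit_weibull_mle(sample, min_n: int = MIN_FIT_SAMPLE) -> DistFit:
    """Two-parameter Weibull MLE (location fixed at zero)."""
    x = _as_intervals(sample)
    _check_fit_sample(x, min_n)
    return _scipy_fit(stats.weibull_min, x, "weibull", {"floc": 0})


def _fit_exponential(x: np.ndarray) -> DistFit:
    return _scipy_fit(stats.expon, x, "exponential", {"floc": 0})


def _fit_lognormal(x: np.ndarray) -> DistFit:
    return _scipy_fit(stats.lognorm, x, "lognormal", {"floc": 0})


def _fit_normal(x: np.ndarray) -> DistFit:
    return _scipy_fit(stats.norm, x, "normal", {})


DEFAULT_CANDIDATES = ("gamma", "weibull", "exponential", "lognormal", "normal")

_FITTERS = {
    "gamma": lambda x: fit_gamma_mle(x),
    "weibull": lambda x: fit_weibull_mle(x),
    "exponential": _fit_exponential,
    "lognormal": _fit_lognormal,
    "normal": _fit_normal,
}


def fit_candidates(sample, candidates=DEFAULT_CANDIDATES) -> list[DistFit]:
    """Fit every named candidate distribution to the same sample."""
    x = _as_intervals(sample)
    return [_FITTERS[name](x) for name in candidates]


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness of fit with parameter-adjusted degrees of freedom."""

    distribution_name: str
    statistic: float
    degrees_of_freedom: int
    p_value: float
    bin_edges: np.ndarray


def default_n_bins(n: int) -> int:
    """Equiprobable-bin count rule: max(6, n // 50), capped at 50."""
    return min(max(6, n // 50), 50)


def chi_square_gof(sample, fitted: DistFit, n_bins: int | None = None) -> GofResult:
    """Pearson chi-square of a sample against a fitted distribution.

    Bins are equiprobable under the fitted distribution, so every bin has
    expected count n / n_bins; the degrees of freedom are
    ``n_bins - 1 - n_estimated_params``.

    Raises
    ------
    ValueError
        If any expected bin count falls below 1 (too many bins), or the
        adjusted degrees of freedom would be < 1.
    """
    x = _as_intervals(sample)
    n = x.size
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    expected_per_bin = n / n_bins
    if expected_per_bin < 1:
        raise ValueError(
            f"expected count per bin {expected_per_bin:.2f} < 1; use fewer bins"
        )
    df = n_bins - 1 - fitted.n_params
    if df < 1:
        raise ValueError("degrees of freedom < 1; use more bins")
    q = np.linspace(0, 1, n_bins + 1)
    edges = np.asarray(fitted.ppf(q), dtype=float)
    edges[0], edges[-1] = -np.inf, np.inf
    bin_idx = np.searchsorted(edges, x, side="right") - 1
    observed = np.bincount(np.clip(bin_idx, 0, n_bins - 1), minlength=n_bins)
    statistic = float(np.sum((observed - expected_per_bin) ** 2) / expected_per_bin)
    p = float(stats.chi2.sf(statistic, df))
    return GofResult(fitted.name, statistic, df, p, edges)


def rank_fits(sample, candidates: list[DistFit], n_bins: int | None = None
              ) -> list[tuple[DistFit, GofResult]]:
    """Order fitted candidates by ascending chi-square statistic.

    All candidates share the same bin-count rule (each binned
    equiprobably under its own fit).  Ties break toward fewer estimated
    parameters, then alphabetical name; the sort is stable.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    scored = [(fit, chi_square_gof(sample, fit, n_bins)) for fit in candidates]
    scored.sort(key=lambda fg: (fg[1].statistic, fg[0].n_params, fg[0].name))
    return scored
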