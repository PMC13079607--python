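"""Gamma-family characterization of MMS peak samples.

The continuous Gamma family in the shape-scale parameterization,

    f(x; a, b) = x^{a-1} e^{-x/b} / (b^a Gamma(a)),   x > 0, a, b > 0,

summarizes a spike-magnitude sample through two interpretable quantities:

* the noise-to-signal ratio NSR = variance / mean = a b^2 / (a b) = b, i.e.
  the scale parameter itself — larger b means a noisier, more dispersed
  process; and
* the skewness 2 / sqrt(a) — a = 1 is the memoryless exponential regime,
  large a approaches Gaussian symmetry.

Across a cohort, the fitted (a, b) pairs of many biorhythms fall on a tight
negatively sloped line in the log10-log10 parameter plane (a scaling power
law), so either parameter predicts the other; :func:`fit_loglog_law`
estimates that line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "GammaFit",
    "FamilyComparison",
    "PowerLawFit",
    "NSRVector",
    "fit_gamma_mle",
    "compare_families",
    "gamma_moments",
    "fit_loglog_law",
    "nsr_skew_summary",
    "delta_params",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood Gamma fit with asymptotic 95% confidence intervals.

    ``degenerate`` flags a zero-variance sample (all values identical), for
    which the scale collapses to 0 and the shape diverges; derived moments are
    then taken from the sample mean.
    """

    shape: float
    scale: float
    ci_shape: tuple[float, float]
    ci_scale: tuple[float, float]
    loglik: float
    n: int
    degenerate: bool = False

    @property
    def mean(self) -> float:
        if self.degenerate:
            return self._const
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return 0.0 if self.degenerate else self.shape * self.scale**2

    @property
    def nsr(self) -> float:
        """Noise-to-signal ratio, variance/mean: equals the scale parameter."""
        return self.scale

    @property
    def skewness(self) -> float:
        return 0.0 if self.degenerate else 2.0 / math.sqrt(self.shape)

    # stash for the degenerate constant (set in fit_gamma_mle)
    _const: float = field(default=0.0, repr=False, compare=False)


@dataclass(frozen=True)
class FamilyComparison:
    """Per-family MLE log-likelihoods on one sample, with ranks (1 = best)."""

    logliks: dict[str, float]
    ranks: dict[str, int]

    @property
    def best(self) -> str:
        return min(self.ranks, key=self.ranks.get)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(scale) on log10(shape) across a cohort."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int


@dataclass(frozen=True)
class NSRVector:
    """Region-wise Gamma NSR and skewness with Euclidean norms from the origin."""

    v1: float
    v2: float
    v3: float
    skew_v1: float
    skew_v2: float
    skew_v3: float

    @property
    def norm(self) -> float:
        return math.sqrt(self.v1**2 + self.v2**2 + self.v3**2)

    @property
    def skew_norm(self) -> float:
        return math.sqrt(self.skew_v1**2 + self.skew_v2**2 + self.skew_v3**2)


def _gamma_loglik(x: np.ndarray, a: float, b: float) -> float:
    return float(np.sum(stats.gamma.logpdf(x, a, scale=b)))


def fit_gamma_mle(peaks: np.ndarray, min_n: int = 30) -> GammaFit:
    """Fit Gamma(shape, scale) by maximum likelihood, with Wald 95% CIs.

    Confidence intervals come from the observed-information asymptotic
    covariance: the per-observation information matrix in (a, b) is
    [[psi'(a), 1/b], [1/b, a/b^2]], inverted and scaled by 1/n.

    A zero-variance sample is returned flagged ``degenerate`` with scale 0
    rather than raising, since heavy regimes of the synthetic generator can
    legitimately produce (near-)constant windows.
    """
    x = np.asarray(peaks, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be one-dimensional")
    if len(x) < min_n:
        raise ValueError(f"sample size {len(x)} below the fitting floor {min_n}")
    if np.any(x <= 0):
        raise ValueError("Gamma fitting requires strictly positive values")
    if np.ptp(x) == 0.0:
        warnings.warn("zero-variance sample: degenerate Gamma fit (scale -> 0)")
        return GammaFit(
            shape=math.inf,
            scale=0.0,
            ci_shape=(math.inf, math.inf),
            ci_scale=(0.0, 0.0),
            loglik=math.inf,
            n=len(x),
            degenerate=True,
            _const=float(x[0]),
        )
    a, _, b = stats.gamma.fit(x, floc=0)
    n = len(x)
    info = np.array([[special.polygamma(1, a), 1.0 / b], [1.0 / b, a / b**2]])
    cov = np.linalg.inv(n * info)
    se_a, se_b = np.sqrt(np.diag(cov))
    return GammaFit(
        shape=float(a),
        scale=float(b),
        ci_shape=(float(a - _Z95 * se_a), float(a + _Z95 * se_a)),
        ci_scale=(float(b - _Z95 * se_b), float(b + _Z95 * se_b)),
        loglik=_gamma_loglik(x, a, b),
        n=n,
    )


def compare_families(peaks: np.ndarray, min_n: int = 30) -> FamilyComparison:
    """MLE log-likelihoods of normal, lognormal, Weibull and Gamma fits.

    All positive-support families are fitted without a location (threshold)
    parameter; the normal is fitted unrestricted.  Only the ranking is
    reported — no automatic selection.
    """
    x = np.asarray(peaks, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"sample size {len(x)} below the fitting floor {min_n}")
    if np.any(x <= 0):
        raise ValueError("family comparison requires strictly positive values")
    lls: dict[str, float] = {}
    mu, sd = stats.norm.fit(x)
    lls["normal"] = float(np.sum(stats.norm.logpdf(x, mu, sd)))
    s, _, sc = stats.lognorm.fit(x, floc=0)
    lls["lognormal"] = float(np.sum(stats.lognorm.logpdf(x, s, scale=sc)))
    c, _, sc = stats.weibull_min.fit(x, floc=0)
    lls["weibull"] = float(np.sum(stats.weibull_min.logpdf(x, c, scale=sc)))
    a, _, b = stats.gamma.fit(x, floc=0)
    lls["gamma"] = _gamma_loglik(x, a, b)
    order = sorted(lls, key=lls.get, reverse=True)
    ranks = {name: i + 1 for i, name in enumerate(order)}
    return FamilyComparison(logliks=lls, ranks=ranks)


def gamma_moments(fit: GammaFit) -> dict[str, float]:
    """Closed-form moments of a fitted Gamma: mean a*b, variance a*b^2,
    NSR = b, skewness = 2/sqrt(a)."""
    return {
        "mean": fit.mean,
        "variance": fit.variance,
        "nsr": fit.nsr,
        "skewness": fit.skewness,
    }


def fit_loglog_law(cohort_fits: list[GammaFit]) -> PowerLawFit:
    """OLS of log10(scale) on log10(shape) across cohort fits.

    Estimates the cohort-level scaling power law linking dispersion (NSR) and
    distribution form: the slope is negative when noisier processes are also
    closer to the memoryless exponential regime.
    """
    fits = [f for f in cohort_fits if not f.degenerate]
    if len(fits) < 3:
        raise ValueError("need at least 3 non-degenerate fits for the log-log law")
    la = np.log10([f.shape for f in fits])
    lb = np.log10([f.scale for f in fits])
    if np.ptp(la) == 0.0:
        raise ValueError("all shapes identical: log-log slope undefined")
    res = stats.linregress(la, lb)
    resid = lb - (res.intercept + res.slope * la)
    dof = max(len(fits) - 2, 1)
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n=len(fits),
    )


def nsr_skew_summary(region_fits: dict[str, GammaFit]) -> NSRVector:
    """Assemble the (V1, V2, V3) NSR vector and paired skewness vector."""
    missing = {"V1", "V2", "V3"} - set(region_fits)
    if missing:
        raise ValueError(f"missing region fits: {sorted(missing)}")
    return NSRVector(
        v1=region_fits["V1"].nsr,
        v2=region_fits["V2"].nsr,
        v3=region_fits["V3"].nsr,
        skew_v1=region_fits["V1"].skewness,
        skew_v2=region_fits["V2"].skewness,
        skew_v3=region_fits["V3"].skewness,
    )


def delta_params(pain, control) -> dict[str, float]:
    """Pain-minus-control differences of NSR/skewness descriptors.

    Accepts two :class:`NSRVector` (per-region and norm deltas) or two
    :class:`GammaFit` (scalar NSR and skewness deltas).  Antisymmetric:
    ``delta_params(x, y) == -delta_params(y, x)`` componentwise.
    """
    if isinstance(pain, NSRVector) and isinstance(control, NSRVector):
        return {
            "dnsr_v1": pain.v1 - control.v1,
            "dnsr_v2": pain.v2 - control.v2,
            "dnsr_v3": pain.v3 - control.v3,
            "dnsr_norm": pain.norm - control.norm,
            "dskew_v1": pain.skew_v1 - control.skew_v1,
            "dskew_v2": pain.skew_v2 - control.skew_v2,
            "dskew_v3": pain.skew_v3 - control.skew_v3,
            "dskew_norm": pain.skew_norm - control.skew_norm,
        }
    if isinstance(pain, GammaFit) and isinstance(control, GammaFit):
        return {
            "dnsr": pain.nsr - control.nsr,
            "dskew": pain.skewness - control.skewness,
        }
    raise TypeError("delta_params expects two NSRVector or two GammaFit objects")
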