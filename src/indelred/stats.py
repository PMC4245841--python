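"""Distributional models for indel sizes and adjacent-variant distances.

Indel sizes are modelled by a Pareto (power-law) distribution with the
location fixed at 1, since the smallest possible indel is one base; the
shape MLE is the closed form ``n / sum(ln x)``.  Distances between
adjacent variants are modelled by a Gamma distribution — the inter-arrival
law of a Gamma count (renewal) process, which reduces to a Poisson process
at shape 1 — with exponential and Weibull fits available for likelihood
comparison.  All four estimators treat the integer observations as draws
from the continuous densities, with no discretisation correction: that is
the estimator the size/distance analyses in this domain conventionally
report.

Zero distances (co-located records) carry no density mass under any of
these families and are excluded before fitting by default.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .io_model import ComputationError, InputError

__all__ = [
    "Family",
    "DistanceSample",
    "SizeSample",
    "FitResult",
    "adjacent_distances",
    "fit_pareto",
    "fit_gamma",
    "fit_exponential",
    "fit_weibull",
    "gamma_mean_variance_ratio",
    "size_histogram",
]

_MAX_ITER = 200
_TOL = 1e-10


class Family(str, enum.Enum):
    PARETO = "pareto"
    GAMMA = "gamma"
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"


@dataclass(frozen=True)
class DistanceSample:
    """Successive differences of sorted variant positions on one chromosome."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SizeSample:
    """Indel lengths in bp; every value is at least 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size and vals.min() < 1:
            raise InputError("indel sizes must be >= 1")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FitResult:
    family: Family
    params: Mapping[str, float]
    n: int
    loglik: float

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "params": dict(self.params),
            "n": self.n,
            "loglik": self.loglik,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def adjacent_distances(
    positions: Sequence[int], drop_nonpositive: bool = True
) -> DistanceSample:
    """Distances between successive sorted positions on one chromosome.

    ``drop_nonpositive`` (default) removes zero distances from co-located
    records; disable it to keep them shifted by +0.5 so that density-based
    fitters still see positive values.
    """
    pos = np.sort(np.asarray(positions, dtype=float).ravel())
    if pos.size < 2:
        raise InputError("need at least 2 positions to form distances")
    diffs = np.diff(pos)
    if drop_nonpositive:
        diffs = diffs[diffs > 0]
    else:
        diffs = np.where(diffs <= 0, diffs + 0.5, diffs)
    return DistanceSample(diffs)


def _positive(values: np.ndarray, what: str) -> np.ndarray:
    if values.size == 0:
        raise InputError(f"empty {what}")
    if values.min() <= 0:
        raise InputError(f"{what} must be strictly positive for fitting")
    return values


def fit_pareto(sample: SizeSample) -> FitResult:
    """Closed-form MLE of the Pareto shape with location fixed at 1.

    alpha_hat = n / sum(ln x); degenerate when every size equals 1.
    """
    x = _positive(sample.values, "size sample")
    sum_log = float(np.sum(np.log(x)))
    if sum_log <= 0.0:
        raise ComputationError(
            "Pareto shape MLE diverges: all sizes equal the location (1)"
        )
    n = sample.n
    alpha = n / sum_log
    loglik = n * math.log(alpha) - (alpha + 1.0) * sum_log
    return FitResult(Family.PARETO, {"shape": alpha}, n, loglik)


def _gamma_profile(alpha: float, s: float) -> float:
    return math.log(alpha) - special.digamma(alpha) - s


def fit_gamma(sample: DistanceSample) -> FitResult:
    """Two-parameter Gamma MLE via the profile equation in the shape.

    At the optimum ``ln(alpha) - psi(alpha) = ln(mean x) - mean(ln x)``
    and the rate is ``alpha / mean x`` (so the fitted mean matches the
    sample mean exactly).  Newton iteration from the moment-style start
    ``0.5 / s`` with a bisection fallback; converged when the shape update
    drops below 1e-10 in log scale.
    """
    x = _positive(sample.values, "distance sample")
    if sample.n < 2:
        raise InputError("need n >= 2 for a Gamma fit")
    if float(np.var(x)) == 0.0:
        raise InputError("zero-variance sample: Gamma fit is degenerate")
    mean = float(np.mean(x))
    mean_log = float(np.mean(np.log(x)))
    s = math.log(mean) - mean_log  # > 0 by Jensen unless degenerate
    alpha = 0.5 / s
    converged = False
    for _ in range(_MAX_ITER):
        f = _gamma_profile(alpha, s)
        fprime = 1.0 / alpha - special.polygamma(1, alpha)
        step = f / fprime
        new_alpha = alpha - step
        if new_alpha <= 0:  # Newton left the domain: bisect instead
            new_alpha = alpha / 2.0 if f < 0 else alpha * 2.0
        if abs(math.log(new_alpha) - math.log(alpha)) < _TOL:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    if not converged:
        raise ComputationError("Gamma shape iteration did not converge")
    beta = alpha / mean
    n = sample.n
    loglik = float(
        n * alpha * math.log(beta)
        - n * special.gammaln(alpha)
        + (alpha - 1.0) * n * mean_log
        - beta * n * mean
    )
    return FitResult(Family.GAMMA, {"shape": alpha, "rate": beta}, n, loglik)


def fit_exponential(sample: DistanceSample) -> FitResult:
    """Exponential rate MLE: the reciprocal sample mean."""
    x = _positive(sample.values, "distance sample")
    mean = float(np.mean(x))
    rate = 1.0 / mean
    n = sample.n
    loglik = n * math.log(rate) - rate * n * mean
    return FitResult(Family.EXPONENTIAL, {"rate": rate}, n, loglik)


def fit_weibull(sample: DistanceSample) -> FitResult:
    """Two-parameter Weibull MLE via the profile likelihood in the shape.

    The scale is eliminated analytically (``scale^k = mean(x^k)``), leaving
    a single monotone equation in the shape k, solved by bracketed root
    finding to the same tolerance policy as the Gamma fit.
    """
    x = _positive(sample.values, "distance sample")
    if sample.n < 2:
        raise InputError("need n >= 2 for a Weibull fit")
    if float(np.var(x)) == 0.0:
        raise InputError("zero-variance sample: Weibull fit is degenerate")
    log_x = np.log(x)
    mean_log = float(np.mean(log_x))

    def profile(k: float) -> float:
        # E_w[ln x] - 1/k - mean(ln x), weights w_i ∝ x_i^k (log-sum-exp)
        z = k * log_x
        z -= z.max()
        w = np.exp(z)
        return float(np.sum(w * log_x) / np.sum(w) - 1.0 / k - mean_log)

    lo, hi = 1e-3, 2.0
    for _ in range(_MAX_ITER):
        if profile(hi) > 0:
            break
        hi *= 2.0
    else:
        raise ComputationError("Weibull shape bracket expansion failed")
    if profile(lo) >= 0:
        raise ComputationError("Weibull profile has no root above shape 1e-3")
    k = float(optimize.brentq(profile, lo, hi, xtol=_TOL, maxiter=_MAX_ITER))
    scale = float(np.exp(special.logsumexp(k * log_x) / k) / sample.n ** (1.0 / k))
    n = sample.n
    loglik = float(
        n * math.log(k)
        - n * k * math.log(scale)
        + (k - 1.0) * n * mean_log
        - np.sum((x / scale) ** k)
    )
    return FitResult(Family.WEIBULL, {"shape": k, "scale": scale}, n, loglik)


def gamma_mean_variance_ratio(
    fit_indel: FitResult, fit_snp: FitResult
) -> tuple[float, float]:
    """Ratios of fitted Gamma means and variances (indel over SNP).

    mean ratio = (a_i/b_i)/(a_s/b_s); variance ratio = (a_i/b_i^2)/(a_s/b_s^2).
    """
    for fit in (fit_indel, fit_snp):
        if fit.family is not Family.GAMMA:
            raise InputError(f"expected Gamma fits, got {fit.family.value}")
    a_i, b_i = fit_indel.params["shape"], fit_indel.params["rate"]
    a_s, b_s = fit_snp.params["shape"], fit_snp.params["rate"]
    mean_ratio = (a_i / b_i) / (a_s / b_s)
    var_ratio = (a_i / b_i**2) / (a_s / b_s**2)
    return mean_ratio, var_ratio


def size_histogram(sample: SizeSample, max_bin: int) -> dict:
    """Integer-binned size counts; sizes above ``max_bin`` pool in 'overflow'."""
    counts: dict = {}
    overflow = 0
    for v in sample.values:
        size = int(v)
        if size > max_bin:
            overflow += 1
        else:
            counts[size] = counts.get(size, 0) + 1
    out = {k: counts[k] for k in sorted(counts)}
    if overflow:
        out["overflow"] = overflow
    return out
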