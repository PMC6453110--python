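"""Resampling and transformation statistics for proportion data.

Covers the three statistical tools the analysis chain relies on:

* bias-corrected and accelerated (BCa) percentile bootstrap confidence
  intervals on across-observer means (20,000 resamples by default);
* the logit transform ``log(y / (1 - y))`` with extreme proportions (exact
  0 or 1) clamped by half the resolution of 24 repetitions, i.e. 1/48,
  before transformation;
* the additivity comparison: on the logit scale, the central-vision bias of
  the widest eccentricity pair (0|8) is compared with the sum of the two
  narrower pairs (0|4 plus 4|8);
* an OLS trend regression of mean proportions against within-condition
  trial number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: half the proportion resolution attainable with 24 repetitions
CLAMP_CONSTANT = 1.0 / 48.0


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings of the bootstrap resampling scheme.

    The resampling unit is the observer: the reported group statistics are
    across-observer means of per-observer proportions, so observers (not
    trials) are drawn with replacement.  ``unit="trial"`` is accepted for
    sensitivity analyses on raw per-trial outcome vectors.
    """

    n_samples: int = 20_000
    confidence: float = 0.95
    seed: int = 0
    unit: str = "observer"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_samples < 1000:
            warnings.warn(
                f"n_samples={self.n_samples} is below the BCa stability "
                "floor of 1000; intervals may be unstable",
                UserWarning,
            )
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.unit not in ("observer", "trial"):
            raise ValueError(f"unknown resampling unit {self.unit!r}")


@dataclass(frozen=True)
class LogitValue:
    y: float
    y_clamped: float
    logit: float
    clamp_constant: float = CLAMP_CONSTANT


def logit_transform(y: float) -> LogitValue:
    """Logit of a proportion, clamping exact 0/1 by 1/48.

    The clamp is applied only at the boundary values (its stated purpose is
    to make proportions of 0 or 1 transformable), never as a universal
    shrinkage of interior proportions.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"proportion {y!r} outside [0, 1]")
    if y == 0.0:
        yc = CLAMP_CONSTANT
    elif y == 1.0:
        yc = 1.0 - CLAMP_CONSTANT
    else:
        yc = y
    return LogitValue(y=y, y_clamped=yc, logit=float(np.log(yc / (1.0 - yc))))


def logit(y: float) -> float:
    """Shorthand: the clamped log-odds value itself."""
    return logit_transform(y).logit


def bca_ci(
    values,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean of ``values``.

    Implements the standard bias-corrected and accelerated percentile
    method: resample with replacement ``n_samples`` times; the bias
    correction ``z0`` is the normal quantile of the fraction of bootstrap
    means below the observed mean, and the acceleration ``a`` comes from the
    jackknife skewness of the mean.  Degenerate inputs (all values equal)
    return a zero-width interval; a degenerate bias correction (observed
    mean at an extreme of the bootstrap distribution) falls back to the
    plain percentile interval with a warning.
    """
    config = config or BootstrapConfig()
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d sample of at least two values")
    if np.ptp(x) == 0.0:
        return float(x[0]), float(x[0])
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = x.size
    alpha = 1.0 - config.confidence
    idx = rng.integers(0, n, size=(config.n_samples, n))
    boot = x[idx].mean(axis=1)
    observed = x.mean()

    frac_below = float(np.mean(boot < observed))
    if frac_below <= 0.0 or frac_below >= 1.0:
        warnings.warn(
            "observed mean at an extreme of the bootstrap distribution; "
            "falling back to percentile bounds",
            UserWarning,
        )
        lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(lo), float(hi)
    z0 = norm.ppf(frac_below)

    # jackknife acceleration
    jack = (observed * n - x) / (n - 1)
    d = jack.mean() - jack
    denom = 6.0 * (d**2).sum() ** 1.5
    a = float((d**3).sum() / denom) if denom > 0 else 0.0

    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    a1 = norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
    a2 = norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boot, [a1, a2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class AdditivityResult:
    """Comparison of summed narrow-pair logits against the wide pair."""

    summed_logit: float
    observed_logit: float
    per_observer_diff: np.ndarray = field(repr=False)
    mean_diff: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0

    @property
    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def additivity_test(
    p_04, p_48, p_08, config: BootstrapConfig | None = None
) -> AdditivityResult:
    """Test logit additivity of the eccentricity biases.

    For each observer the logits of the 0|4 and 4|8 proportions are summed
    and compared with the logit of the 0|8 proportion; the mean of the
    per-observer differences (sum minus observed) gets a BCa bootstrap CI.
    A CI covering zero is consistent with additive biases.
    """
    p_04, p_48, p_08 = (np.asarray(p, dtype=float) for p in (p_04, p_48, p_08))
    if not (p_04.shape == p_48.shape == p_08.shape):
        raise ValueError("the three proportion vectors must share observers")
    l04 = np.array([logit(v) for v in p_04])
    l48 = np.array([logit(v) for v in p_48])
    l08 = np.array([logit(v) for v in p_08])
    diff = l04 + l48 - l08
    if np.ptp(diff) == 0.0:
        lo = hi = float(diff[0])
    else:
        lo, hi = bca_ci(diff, config)
    return AdditivityResult(
        summed_logit=float((l04 + l48).mean()),
        observed_logit=float(l08.mean()),
        per_observer_diff=diff,
        mean_diff=float(diff.mean()),
        ci_low=lo,
        ci_high=hi,
    )


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    n_points: int


def trend_regression(proportions, trial_numbers=None) -> TrendResult:
    """OLS line through (within-condition trial number, mean proportion).

    ``proportions`` are the across-observer mean proportions at each
    within-condition trial number (1-based by default).  Returns the slope,
    intercept and the 95% confidence interval of the slope.
    """
    y = np.asarray(proportions, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need at least three trial-number means")
    x = (
        np.arange(1, y.size + 1, dtype=float)
        if trial_numbers is None
        else np.asarray(trial_numbers, dtype=float)
    )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return TrendResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        n_points=int(y.size),
    )
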