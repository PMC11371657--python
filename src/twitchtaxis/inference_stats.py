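"""Exact count statistics for reversal rates and event proportions.

Reversal detection yields a small number of events (n_r) across a very
large number of trajectory points (n_t), so reversals are modelled as a
Poisson process per trajectory point.  This module provides the exact
(Garwood) Poisson rate interval, the conditional exact two-sample Poisson
test, the exact binomial test (minimum-likelihood two-sided convention)
and Wilson score intervals for proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class RateEstimate:
    """Poisson rate estimate with an exact confidence interval.

    ``rate`` and the interval bounds are events per unit exposure (per
    trajectory point when ``n_t`` counts frames).
    """

    n_r: int
    n_t: float
    rate: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    def per_minute(self, frame_rate: float) -> "RateEstimate":
        """Rescale a per-frame rate to per minute given frames/min."""
        f = float(frame_rate)
        return RateEstimate(self.n_r, self.n_t / f, self.rate * f,
                            self.ci_low * f, self.ci_high * f, self.conf_level)


def poisson_rate_ci(n_r: int, n_t: float, conf: float = 0.95) -> RateEstimate:
    """Exact (Garwood) confidence interval for a Poisson rate.

    The interval for the Poisson mean uses gamma quantiles,
    [gamma_{a/2}(n_r), gamma_{1-a/2}(n_r + 1)], scaled by the exposure
    ``n_t``; the lower bound is 0 when no events were observed.
    """
    if n_t <= 0:
        raise ValueError("exposure n_t must be positive")
    if n_r < 0:
        raise ValueError("n_r must be nonnegative")
    alpha = 1.0 - conf
    lo = 0.0 if n_r == 0 else stats.gamma.ppf(alpha / 2.0, n_r) / n_t
    hi = stats.gamma.ppf(1.0 - alpha / 2.0, n_r + 1) / n_t
    return RateEstimate(int(n_r), float(n_t), n_r / n_t, float(lo), float(hi),
                        conf)


def _binom_pvalue(k: int, n: int, p: float, alternative: str) -> float:
    """Exact binomial p-value by tail summation.

    Two-sided uses the minimum-likelihood convention: sum the probabilities
    of all outcomes no more probable than the observed one (with a small
    relative tolerance against floating-point ties).
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("require 0 <= p <= 1")
    ks = np.arange(n + 1)
    pmf = stats.binom.pmf(ks, n, p)
    if alternative == "greater":
        pval = pmf[k:].sum()
    elif alternative == "less":
        pval = pmf[: k + 1].sum()
    elif alternative == "two-sided":
        pval = pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum()
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return float(min(1.0, pval))


def exact_binomial_test(k: int, n: int, p0: float = 0.5,
                        alternative: str = "two-sided") -> float:
    """Exact binomial test of k successes in n trials against probability p0."""
    return _binom_pvalue(int(k), int(n), float(p0), alternative)


def exact_poisson_two_sample(n1: int, t1: float, n2: int, t2: float,
                             alternative: str = "two-sided") -> float:
    """Conditional exact test of equal Poisson rates between two samples.

    Conditional on the total count N = n1 + n2, n1 is binomial(N,
    t1/(t1+t2)) under the null of equal rates; the p-value is the exact
    binomial tail (or minimum-likelihood two-sided sum).  ``alternative``
    refers to the rate of sample 1 relative to sample 2.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("exposures must be positive")
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise ValueError("need nonnegative counts with n1 + n2 > 0")
    return _binom_pvalue(int(n1), int(n1 + n2), t1 / (t1 + t2), alternative)


def proportion_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, bounded in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def format_rate_report(estimates: dict) -> str:
    """Plain-text report of labelled RateEstimates (one line per interval)."""
    lines = []
    for label, est in estimates.items():
        lines.append(
            f"{label:<8s} n_r={est.n_r:<8d} n_t={est.n_t:<12.0f} "
            f"rate={est.rate:.3e} "
            f"ci=[{est.ci_low:.3e}, {est.ci_high:.3e}] "
            f"conf={est.conf_level:.2f}")
    return "\n".join(lines)
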