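"""Estimation layer: prevalence, intervals, suppression, and the named tests.

Every statistic reported by the surveillance tables flows through this module:

* binomial prevalence per 1,000 with Wilson score 95% confidence intervals,
* prevalence ratios with log-normal (Katz) intervals,
* suppression of estimates whose relative standard error exceeds 30%,
* Pearson chi-square comparison of proportions,
* the Woolf (Mantel-Haenszel) test of homogeneity of prevalence ratios
  across strata,
* the Cochran-Armitage test for trend in prevalence over ordered groups,
* a permutation test for differences in medians (exhaustive when feasible).

Internal arithmetic is never rounded; rounding to one decimal,
half-away-from-zero, happens only at the reporting boundary via
:func:`round_half_away`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "PrevalenceEstimate",
    "RatioEstimate",
    "round_half_away",
    "one_in_n",
    "wilson_interval",
    "prevalence",
    "prevalence_ratio",
    "suppress",
    "chi_square_proportions",
    "woolf_homogeneity",
    "cochran_armitage_trend",
    "permutation_median_test",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-wide constants.

    alpha
        Two-sided significance level; tests with p < alpha are flagged.
    z
        Normal quantile used for 95% intervals. Fixed at the 97.5th
        percentile to full precision rather than the textbook 1.96; the
        difference is below the one-decimal reporting resolution.
    rse_threshold
        Estimates whose relative standard error exceeds this are suppressed.
    n_permutations
        Monte-Carlo draws for the permutation median test when exhaustive
        enumeration is infeasible.
    permutation_seed
        Seed for the Monte-Carlo permutation stream (mandatory so reruns
        reproduce p-values bit-for-bit).
    exhaustive_limit
        Enumerate all label arrangements when their count is at most this.
    """

    alpha: float = 0.05
    z: float = 1.959964
    rse_threshold: float = 0.30
    n_permutations: int = 10_000
    permutation_seed: int = 0
    exhaustive_limit: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


DEFAULT_CONFIG = AnalysisConfig()


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (23.55 -> 23.6, -23.55 -> -23.6).

    Python's built-in round() uses banker's rounding, which would turn a
    printed-table boundary like 4.25 into 4.2 instead of 4.3.
    """
    if not math.isfinite(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def one_in_n(numerator: float, denominator: float) -> int:
    """'One in N' phrasing of a proportion: round(denominator / numerator)."""
    if numerator <= 0:
        raise ValidationError("numerator must be positive for a one-in-N rate")
    return int(round_half_away(denominator / numerator, 0))


@dataclass
class PrevalenceEstimate:
    """A count-based prevalence with Wilson interval, on the per-1,000 scale.

    All stored values are unrounded; use :func:`round_half_away` when
    rendering. ``rse`` is the binomial relative standard error
    sqrt(p(1-p)/n)/p (infinite when the numerator is zero).
    """

    numerator: int
    denominator: float
    per_1000: float
    ci_low_per_1000: float
    ci_high_per_1000: float
    rse: float
    suppressed: bool

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator


@dataclass
class RatioEstimate:
    """Ratio of two prevalences with a log-normal (Katz) interval."""

    ratio: float
    ci_low: float
    ci_high: float
    suppressed: bool


def _check_counts(numerator: float, denominator: float) -> None:
    if denominator <= 0:
        raise ValidationError(f"denominator must be positive, got {denominator}")
    if numerator < 0:
        raise ValidationError(f"numerator must be nonnegative, got {numerator}")
    if numerator > denominator:
        raise ValidationError("numerator exceeds denominator")


def wilson_interval(
    numerator: float,
    denominator: float,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, scaled per 1,000.

    The interval inverts the score test: centre (p + z²/2n)/(1 + z²/n),
    half-width z·sqrt(p(1-p)/n + z²/4n²)/(1 + z²/n). The lower bound is
    exactly 0 when the numerator is 0.
    """
    _check_counts(numerator, denominator)
    n = float(denominator)
    p = numerator / n
    z2 = cfg.z * cfg.z
    denom = 1.0 + z2 / n
    centre = (p + z2 / (2.0 * n)) / denom
    half = cfg.z * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n)) / denom
    # the bounds are algebraically within [0, 1] with exact endpoints at
    # p = 0 and p = 1; clamp float jitter accordingly
    low = 0.0 if numerator == 0 else max(0.0, 1000.0 * (centre - half))
    high = 1000.0 if numerator == denominator else min(1000.0, 1000.0 * (centre + half))
    return low, high


def prevalence(
    numerator: int,
    denominator: float,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> PrevalenceEstimate:
    """Prevalence per 1,000 with Wilson 95% CI and RSE-based suppression."""
    _check_counts(numerator, denominator)
    p = numerator / denominator
    lo, hi = wilson_interval(numerator, denominator, cfg)
    if numerator == 0:
        rse = math.inf
    else:
        rse = math.sqrt(p * (1.0 - p) / denominator) / p
    est = PrevalenceEstimate(
        numerator=int(numerator),
        denominator=float(denominator),
        per_1000=1000.0 * p,
        ci_low_per_1000=lo,
        ci_high_per_1000=hi,
        rse=rse,
        suppressed=False,
    )
    return suppress(est, cfg)


def suppress(estimate, cfg: AnalysisConfig = DEFAULT_CONFIG):
    """Apply the RSE > threshold suppression rule to an estimate.

    For :class:`PrevalenceEstimate` the flag is set from its own RSE; for
    :class:`RatioEstimate` suppression must already have been propagated
    from the component estimates, so the estimate is returned unchanged.
    The reporting layer renders suppressed cells as an em dash.
    """
    if isinstance(estimate, PrevalenceEstimate):
        flagged = estimate.rse > cfg.rse_threshold
        if flagged and not estimate.suppressed:
            logger.warning(
                "suppressing estimate %d/%.1f (RSE %.3f > %.2f)",
                estimate.numerator,
                estimate.denominator,
                estimate.rse,
                cfg.rse_threshold,
            )
        return replace(estimate, suppressed=flagged)
    return estimate


def prevalence_ratio(
    a: PrevalenceEstimate,
    b: PrevalenceEstimate,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> RatioEstimate:
    """Ratio of two prevalences with a log-normal (Katz) 95% interval.

    CI = exp(ln R ± z·sqrt(1/x1 − 1/n1 + 1/x2 − 1/n2)) on the unrounded
    prevalences. Suppression propagates: a ratio built from any suppressed
    component is itself suppressed.
    """
    if b.numerator == 0:
        raise ValidationError("comparison prevalence has zero numerator; ratio undefined")
    if a.numerator == 0:
        # Ratio is 0 with a degenerate lower bound; always suppressed
        # because the numerator estimate has infinite RSE.
        return RatioEstimate(ratio=0.0, ci_low=0.0, ci_high=math.inf, suppressed=True)
    ratio = a.per_1000 / b.per_1000
    se = math.sqrt(
        1.0 / a.numerator
        - 1.0 / a.denominator
        + 1.0 / b.numerator
        - 1.0 / b.denominator
    )
    log_r = math.log(ratio)
    return RatioEstimate(
        ratio=ratio,
        ci_low=math.exp(log_r - cfg.z * se),
        ci_high=math.exp(log_r + cfg.z * se),
        suppressed=a.suppressed or b.suppressed,
    )


def chi_square_proportions(table) -> tuple[float, int, float]:
    """Pearson chi-square test comparing proportions across a 2×k table.

    No continuity correction; df = k − 1; p from the upper tail.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValidationError(f"expected a 2×k table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("counts must be nonnegative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValidationError("all row and column margins must be positive")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def woolf_homogeneity(
    strata: Sequence[tuple[float, float, float, float]],
) -> tuple[float, int, float]:
    """Woolf (Mantel-Haenszel) test of homogeneity of prevalence ratios.

    Each stratum is (a_num, a_den, b_num, b_den). Strata with a zero
    numerator on either side are excluded (with a warning) because their
    log ratio is undefined. With weights
    w_i = 1 / (1/a_num − 1/a_den + 1/b_num − 1/b_den), the statistic is
    Σ w_i (ln R_i − ln R̄)² against chi-square with (#strata − 1) df, where
    ln R̄ is the weighted mean log ratio.
    """
    usable = []
    for i, (an, ad, bn, bd) in enumerate(strata):
        _check_counts(an, ad)
        _check_counts(bn, bd)
        if an == 0 or bn == 0:
            logger.warning("excluding stratum %d with zero numerator from Woolf test", i)
            continue
        usable.append((float(an), float(ad), float(bn), float(bd)))
    if len(usable) < 2:
        raise ValidationError("Woolf homogeneity needs at least 2 usable strata")
    w = np.array([1.0 / (1.0 / an - 1.0 / ad + 1.0 / bn - 1.0 / bd) for an, ad, bn, bd in usable])
    log_r = np.array([math.log((an / ad) / (bn / bd)) for an, ad, bn, bd in usable])
    pooled = float(np.sum(w * log_r) / np.sum(w))
    stat = float(np.sum(w * (log_r - pooled) ** 2))
    df = len(usable) - 1
    return stat, df, float(sps.chi2.sf(stat, df))


def cochran_armitage_trend(
    cases: Sequence[float],
    denominators: Sequence[float],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Cochran-Armitage test for trend in binomial proportions.

    Groups are ordered (SES tertiles low/medium/high) with equally spaced
    scores 0, 1, 2 by default. Returns (z, two-sided p). Degenerate inputs
    (no cases, or all cases) give z = 0, p = 1.
    """
    r = np.asarray(cases, dtype=float)
    n = np.asarray(denominators, dtype=float)
    if r.shape != n.shape or r.ndim != 1 or len(r) < 2:
        raise ValidationError("cases and denominators must be 1-D with equal length >= 2")
    if (n <= 0).any():
        raise ValidationError("denominators must be positive")
    if (r < 0).any() or (r > n).any():
        raise ValidationError("cases must lie in [0, denominator]")
    s = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    big_n = n.sum()
    big_r = r.sum()
    if big_r == 0 or big_r == big_n:
        return 0.0, 1.0
    p_bar = big_r / big_n
    num = float(np.sum(s * (r - n * p_bar)))
    var = p_bar * (1.0 - p_bar) * (np.sum(n * s * s) - np.sum(n * s) ** 2 / big_n)
    z = num / math.sqrt(var)
    return z, float(2.0 * sps.norm.sf(abs(z)))


def _median(values: np.ndarray) -> float:
    # np.median averages the two central order statistics for even sizes,
    # which is the convention the half-month medians in the tables imply.
    return float(np.median(values))


def permutation_median_test(
    x: Sequence[float],
    y: Sequence[float],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[float, float]:
    """Permutation test for a difference in medians.

    Statistic: |median(x) − median(y)|. When the number of distinct label
    arrangements C(nx+ny, nx) is at most ``cfg.exhaustive_limit``, all
    arrangements are enumerated and the p-value is exact; otherwise labels
    are permuted ``cfg.n_permutations`` times with the configured seed and
    p = (#{permuted ≥ observed} + 1) / (n_permutations + 1).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValidationError("both samples must be non-empty")
    observed = abs(_median(xa) - _median(ya))
    pooled = np.concatenate([xa, ya])
    n, nx = pooled.size, xa.size
    tol = 1e-9
    total = math.comb(n, nx)
    if total <= cfg.exhaustive_limit:
        count = 0
        idx = np.arange(n)
        for combo in itertools.combinations(idx, nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            stat = abs(_median(pooled[mask]) - _median(pooled[~mask]))
            if stat >= observed - tol:
                count += 1
        return observed, count / total
    rng = np.random.default_rng(cfg.permutation_seed)
    count = 0
    chunk = 2_000
    done = 0
    while done < cfg.n_permutations:
        m = min(chunk, cfg.n_permutations - done)
        # each row is an independent uniform permutation of the pooled sample
        order = np.argsort(rng.random((m, n)), axis=1)
        perm = pooled[order]
        stat = np.abs(np.median(perm[:, :nx], axis=1) - np.median(perm[:, nx:], axis=1))
        count += int(np.sum(stat >= observed - tol))
        done += m
    return observed, (count + 1) / (cfg.n_permutations + 1)
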