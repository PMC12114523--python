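"""Resampling statistics used throughout the analyses.

Four procedures, mirroring how the measurements are compared:

- **Paired sign-flip permutation test** for paired data (day-1 vs day-2
  dynamicity, round vs flat calibers).  The statistic is the mean paired
  difference; the null flips the sign of each difference independently.
  All 2ⁿ assignments are enumerated when n ≤ 20, otherwise a seeded Monte
  Carlo with the observed assignment included ((b+1)/(B+1), so p is never
  0).  Two-sided throughout.
- **Mann–Whitney U** for independent samples (dividing cell vs neighbors),
  with midranks for ties; exact by enumerating all C(n+m, n) labelings when
  n+m ≤ 14 (tie-aware), otherwise normal approximation with tie-corrected
  variance and continuity correction.
- **Paired mean difference with bootstrap 95% CI** (estimation statistics):
  bias-corrected-and-accelerated (BCa) intervals with a percentile fallback
  when the acceleration is undefined; the method used is recorded.
- **Ordinary least-squares regression** with R² for caliber–caliber and
  symmetry–caliber relationships.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "paired_permutation_test",
    "mann_whitney_u",
    "paired_mean_difference_ci",
    "linregress_r2",
]

_REL_TOL = 1e-12


@dataclass
class PairedSample:
    """Paired differences (value2 − value1) with optional location labels."""

    differences: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.differences = np.asarray(self.differences, dtype=float).ravel()
        if self.differences.size < 2:
            raise ValueError("need at least 2 paired differences")
        if not np.all(np.isfinite(self.differences)):
            raise ValueError("differences must be finite")
        if self.labels is not None and len(self.labels) != self.differences.size:
            raise ValueError("labels length mismatch")


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    effect_size: float
    ci_low: float
    ci_high: float
    method: str
    n: int
    exact: bool
    degenerate: bool = False

    def to_record(self, comparison: str = "") -> dict:
        return {
            "comparison": comparison,
            "test": self.method,
            "statistic": self.statistic,
            "p": self.p_value,
            "effect_size": self.effect_size,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "exact": self.exact,
        }


# --------------------------------------------------------------------------
# paired sign-flip permutation test
# --------------------------------------------------------------------------


def _all_signflip_means(d: np.ndarray) -> np.ndarray:
    """Means of d under all 2ⁿ sign assignments, by incremental doubling."""
    sums = np.zeros(1)
    for v in d:
        sums = np.concatenate([sums + v, sums - v])
    return sums / d.size


def paired_permutation_test(
    sample: PairedSample,
    reps: int = 10_000,
    seed: int | None = None,
    exact_max_n: int = 20,
) -> TestResult:
    """Two-sided paired permutation test on the mean difference.

    Exact enumeration of all 2ⁿ sign assignments for n ≤ ``exact_max_n``;
    otherwise seeded Monte Carlo over ``reps`` random assignments with the
    observed one included in both numerator and denominator.
    """
    d = sample.differences
    n = d.size
    obs = float(np.mean(d))
    tol = _REL_TOL * max(np.max(np.abs(d)), 1.0)
    if np.all(d == 0):
        return TestResult(
            "mean difference", obs, 1.0, obs, 0.0, 0.0,
            "paired permutation (degenerate)", n, True, degenerate=True,
        )
    if n <= exact_max_n:
        null = _all_signflip_means(d)
        p = float(np.mean(np.abs(null) >= abs(obs) - tol))
        method, exact = "paired permutation (exact)", True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(reps, n))
        null = signs @ d / n
        b = int(np.sum(np.abs(null) >= abs(obs) - tol))
        p = (b + 1) / (reps + 1)
        method, exact = "paired permutation (monte carlo)", False
    return TestResult("mean difference", obs, p, obs, math.nan, math.nan, method, n, exact)


# --------------------------------------------------------------------------
# Mann–Whitney U
# --------------------------------------------------------------------------


def _u_from_ranks(rank_sum_x: float, n: int) -> float:
    return rank_sum_x - n * (n + 1) / 2.0


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U with midranks for ties.

    ``mode``: "exact" enumerates all C(n+m, n) group labelings (tie-aware),
    "approx" uses the tie-corrected normal approximation with continuity
    correction, "auto" picks exact when n+m ≤ 14.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_from_ranks(float(np.sum(ranks[:n])), n)
    center = n * m / 2.0
    if mode == "auto":
        mode = "exact" if n + m <= 14 else "approx"

    if mode == "exact":
        dev_obs = abs(u_obs - center)
        total = 0
        hits = 0
        for idx in combinations(range(n + m), n):
            u = _u_from_ranks(float(np.sum(ranks[list(idx)])), n)
            total += 1
            if abs(u - center) >= dev_obs - 1e-9:
                hits += 1
        p = hits / total
        method, exact = "Mann-Whitney U (exact enumeration)", True
    else:
        # tie-corrected variance
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / ((n + m) * (n + m - 1.0))
        var = n * m / 12.0 * ((n + m + 1.0) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - center) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
        method, exact = "Mann-Whitney U (normal approx, tie-corrected)", False
    effect = float(np.median(x) - np.median(y))
    return TestResult("U", float(u_obs), float(p), effect, math.nan, math.nan, method, n + m, exact)


# --------------------------------------------------------------------------
# paired mean difference with bootstrap CI (estimation statistics)
# --------------------------------------------------------------------------


def paired_mean_difference_ci(
    sample: PairedSample,
    reps: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Paired mean difference and seeded bootstrap 95% CI (BCa).

    BCa is the convention of the common estimation-statistics tools; when
    the acceleration or bias correction is undefined (degenerate resamples)
    the percentile interval is reported instead, and the method tag records
    which was used.  Constant differences give a zero-width CI.
    """
    d = sample.differences
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a bootstrap CI")
    obs = float(np.mean(d))
    if np.all(d == d[0]):
        return TestResult(
            "mean difference", obs, math.nan, obs, obs, obs,
            "bootstrap (degenerate: constant differences)", n, False, degenerate=True,
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boots = d[idx].mean(axis=1)

    method = "bootstrap BCa"
    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    prop = np.mean(boots < obs) + 0.5 * np.mean(boots == obs)
    if prop <= 0.0 or prop >= 1.0:
        method = "bootstrap percentile (BCa undefined)"
        lo, hi = np.quantile(boots, [lo_q, hi_q])
    else:
        z0 = sps.norm.ppf(prop)
        # acceleration from the jackknife
        jack = (np.sum(d) - d) / (n - 1)
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        if den == 0:
            method = "bootstrap percentile (acceleration undefined)"
            lo, hi = np.quantile(boots, [lo_q, hi_q])
        else:
            a = num / den
            z_lo, z_hi = sps.norm.ppf([lo_q, hi_q])
            def adj(z_a):
                num_ = z0 + z_a
                return sps.norm.cdf(z0 + num_ / (1.0 - a * num_))
            lo, hi = np.quantile(boots, [adj(z_lo), adj(z_hi)])
    return TestResult(
        "mean difference", obs, math.nan, obs, float(lo), float(hi), method, n, False
    )


# --------------------------------------------------------------------------
# OLS regression
# --------------------------------------------------------------------------


def linregress_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares fit; returns (slope, intercept, R²).

    R² = 1 − SS_res/SS_tot; a response with zero variance is reported as
    R² = 0 (degenerate — there is nothing to explain).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.var(x) == 0:
        raise ValueError("var(x) must be positive")
    if np.var(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
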