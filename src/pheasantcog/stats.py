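"""Association and paired-comparison statistics.

One-way intraclass correlation (chick vs adult consistency), Spearman
rank correlation (metric vs mean Elo-rating), the Wilcoxon signed-rank
test (paired condition contrast), and z-standardization. All tests are
two-sided.

The signed-rank zero/tie policy is fixed: zero differences are dropped
before ranking; the exact null distribution is used only when no zeros
were dropped and no magnitudes tie, otherwise a normal approximation
with continuity correction (and midrank tie correction) is applied.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import stats as sps


@dataclasses.dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int
    k: int
    degenerate: bool = False


@dataclasses.dataclass
class SpearmanResult:
    r_s: float
    p: float
    n: int
    method: str  # "exact-permutation" | "large-sample"


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float  # positive-rank sum W+
    n_used: int  # after zero removal
    p: float
    method: str  # "exact" | "normal-cc"


def icc_oneway(pairs: list[tuple[float, float]], alpha: float = 0.05) -> ICCResult:
    """One-way random-effects intraclass correlation, ICC(1).

    From one-way ANOVA mean squares with subjects as groups and the two
    measurements as repeats:
    ``ICC = (MS_among - MS_within) / (MS_among + (k-1) MS_within)``,
    with an F-distribution confidence interval. Negative estimates are
    reported raw.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    if np.isnan(arr).any():
        raise ValueError("pairs contain missing values")
    n, k = arr.shape
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    row_means = arr.mean(axis=1)
    grand = arr.mean()
    ms_among = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_within = np.sum((arr - row_means[:, None]) ** 2) / (n * (k - 1))
    degenerate = ms_among == 0.0
    if ms_among == 0.0 and ms_within == 0.0:
        return ICCResult(float("nan"), float("nan"), float("nan"), n, k, degenerate=True)
    if ms_within == 0.0:
        return ICCResult(1.0, 1.0, 1.0, n, k)
    icc = (ms_among - ms_within) / (ms_among + (k - 1) * ms_within)
    f_obs = ms_among / ms_within
    df1, df2 = n - 1, n * (k - 1)
    f_upper = sps.f.ppf(1 - alpha / 2, df1, df2)
    f_lower_q = sps.f.ppf(1 - alpha / 2, df2, df1)
    fl = f_obs / f_upper
    fu = f_obs * f_lower_q
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), n, k, degenerate=degenerate)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p by full enumeration over pairings (n <= 9)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2, axis=1))
    r_all = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with midrank ties, two-sided p.

    Exact permutation p (full n! enumeration) for n <= ``exact_max_n``;
    the large-sample t approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    r_s = float(res.statistic)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, r_s)
        method = "exact-permutation"
    else:
        p = float(res.pvalue)
        method = "large-sample"
    return SpearmanResult(r_s=r_s, p=min(p, 1.0), n=n, method=method)


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are removed; magnitudes are midranked. The exact
    two-sided p is used when no zeros were removed and no magnitudes
    tie; otherwise the normal approximation with continuity correction.
    """
    d = np.asarray(differences, float)
    if len(d) == 0:
        raise ValueError("empty difference vector")
    nonzero = d[d != 0]
    n_used = len(nonzero)
    if n_used == 0:
        raise ValueError("all differences are zero")
    had_zeros = n_used < len(d)
    has_ties = len(np.unique(np.abs(nonzero))) < n_used
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if not had_zeros and not has_ties:
        res = sps.wilcoxon(nonzero, alternative="two-sided", method="exact")
        return WilcoxonResult(w_plus, n_used, float(res.pvalue), "exact")
    res = sps.wilcoxon(
        nonzero, alternative="two-sided", method="approx", correction=True
    )
    return WilcoxonResult(w_plus, n_used, float(res.pvalue), "normal-cc")


def standardize(values) -> np.ndarray:
    """z-scores: mean 0, sample (ddof=1) standard deviation 1."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread; z-scores undefined")
    return (v - v.mean()) / sd
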