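"""Nonparametric statistical engine for the cohort analysis.

All tests are two-sided.  Small samples take exact enumeration paths
(Wilcoxon signed rank n <= 15, Mann-Whitney m+n <= 20, Spearman n <= 8,
Fisher always exact); larger samples use the standard normal/t
approximations with tie corrections and continuity corrections.  The
two-sided Fisher rule is the point-probability convention: sum the
probabilities of all tables with the observed margins whose probability does
not exceed the observed table's (with 1e-7 relative slack for
floating-point ties).

No multiple-testing correction is applied anywhere; every comparison is
reported at its nominal level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.stats import hypergeom, rankdata

__all__ = [
    "StatResult",
    "ContingencyTable2x2",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "spearman_rho",
    "fisher_exact_2x2",
    "elevated_nfl_threshold",
    "paired_t_test",
]

_FISHER_SLACK = 1e-7


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    n: int
    effect: dict = field(default_factory=dict)
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(float(self.p_value), 1.0)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "effect": {k: (float(v) if np.isscalar(v) else v) for k, v in self.effect.items()},
            "method": self.method,
        }


@dataclass
class ContingencyTable2x2:
    """2x2 counts: rows = g-ratio stratum, columns = elevated NfL yes/no."""

    a: int  # row 1 / col 1
    b: int  # row 1 / col 2
    c: int  # row 2 / col 1
    d: int  # row 2 / col 2
    row_labels: tuple[str, str] = ("abnormal_g", "normal_g")
    col_labels: tuple[str, str] = ("nfl_elevated", "nfl_not_elevated")

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def to_dict(self) -> dict:
        return {
            "cells": [[self.a, self.b], [self.c, self.d]],
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
        }


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 15) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Pass paired samples ``(x, y)`` or precomputed differences as ``x``.
    Zero differences are dropped; tied absolute differences get mid-ranks.
    For n <= ``exact_max_n`` the null distribution of W+ is enumerated over
    all 2^n sign assignments (valid under ties); otherwise the normal
    approximation with continuity correction and a tie-corrected variance is
    used.  Reports both the approximate Z and the rank-biserial correlation.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, 0, method="degenerate")
    if n < 5:
        warnings.warn(f"only {n} nonzero differences; test has little power", stacklevel=2)

    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    w_minus = float(r[d < 0].sum())
    mu = r.sum() / 2.0
    sigma2 = float((r**2).sum()) / 4.0
    z = (w_plus - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    rb = (w_plus - w_minus) / (w_plus + w_minus)

    if n <= exact_max_n:
        # all sign assignments of the observed (possibly tied) ranks
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        w_all = signs @ r
        p = float(np.mean(np.abs(w_all - mu) >= abs(w_plus - mu) - 1e-12))
        method = "exact"
    else:
        cc = 0.5 * np.sign(w_plus - mu)
        zc = (w_plus - mu - cc) / np.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(zc)))
        method = "normal_approx"
    return StatResult(
        "wilcoxon_signed_rank", w_plus, min(p, 1.0), n,
        effect={"z": float(z), "rank_biserial_r": float(rb), "w_minus": w_minus},
        method=method,
    )


def paired_t_test(x, y) -> StatResult:
    """Two-sided paired t-test (comparator; the primary paired test is Wilcoxon)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = sps.ttest_rel(x, y)
    d = x - y
    return StatResult(
        "paired_t_test", float(t), float(p), x.size,
        effect={"mean_difference": float(d.mean())}, method="t",
    )


def mann_whitney_u(a, b, exact_max_total: int = 20) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all C(m+n, m) group assignments of the pooled
    mid-ranks when m + n <= ``exact_max_total``; otherwise normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    r = rankdata(pooled)
    u_a = float(r[:m].sum() - m * (m + 1) / 2.0)
    mu = m * n / 2.0

    if m + n <= exact_max_total:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(m + n), m)),
            dtype=int,
        ).reshape(-1, m)
        u_all = r[idx].sum(axis=1) - m * (m + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_a - mu) - 1e-12))
        method = "exact"
    else:
        N = m + n
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
        sigma2 = m * n / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            p, method = 1.0, "degenerate"
        else:
            cc = 0.5 * np.sign(u_a - mu)
            z = (u_a - mu - cc) / np.sqrt(sigma2)
            p = float(2.0 * sps.norm.sf(abs(z)))
            method = "normal_approx"
    return StatResult(
        "mann_whitney_u", u_a, min(p, 1.0), m + n,
        effect={
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "rank_biserial_r": float(2.0 * u_a / (m * n) - 1.0),
        },
        method=method,
    )


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def spearman_rho(x, y, exact_max_n: int = 8) -> StatResult:
    """Spearman rank correlation with mid-ranks for ties.

    Exact permutation p for n <= ``exact_max_n``; otherwise the
    t-distribution approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 5:
        warnings.warn(f"n = {n} is very small for a correlation test", stacklevel=2)
    rx, ry = rankdata(x), rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = np.array([_rho_from_ranks(rx, ry[p]) for p in perms])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact_permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
        method = "t_approx"
    return StatResult("spearman_rho", rho, min(p, 1.0), n, effect={"rho": rho}, method=method)


def fisher_exact_2x2(table: ContingencyTable2x2) -> StatResult:
    """Two-sided Fisher's exact test (point-probability rule).

    p = sum of hypergeometric probabilities, over all tables with the
    observed margins, of tables no more probable than the observed one.
    A zero margin gives p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.total
    row1, col1 = a + b, a + c
    if N == 0 or row1 in (0, N) or col1 in (0, N):
        return StatResult("fisher_exact_2x2", 0.0, 1.0, N, method="degenerate_margin")
    ks = np.arange(max(0, row1 + col1 - N), min(row1, col1) + 1)
    pmf = hypergeom.pmf(ks, N, row1, col1)
    p_obs = hypergeom.pmf(a, N, row1, col1)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_SLACK)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return StatResult(
        "fisher_exact_2x2", float(odds), min(p, 1.0), N,
        effect={
            "proportion_row1": a / row1,
            "proportion_row2": c / (c + d) if (c + d) else np.nan,
        },
        method="exact",
    )


def elevated_nfl_threshold(control_nfl, min_controls: int = 10) -> float:
    """Elevated-NfL cutoff: control mean + 3 sample SDs (n-1 denominator)."""
    vals = np.asarray(control_nfl, dtype=float)
    if vals.size == 0:
        raise ValueError("no control NfL values")
    if vals.size < min_controls:
        warnings.warn(
            f"only {vals.size} controls; the 3-SD threshold is unstable", stacklevel=2
        )
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(vals.mean() + 3.0 * sd)
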