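"""Significance machinery: F-test-gated two-sample t-tests with star labels.

The choice between the pooled-variance and the Welch (unequal-variance)
t-test is made by a preliminary two-sided variance-ratio F-test at
``alpha_var`` (default 0.05). One-tailed tests require the caller to state
the hypothesized direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientReplicatesError

__all__ = [
    "StatResult",
    "f_test_equal_variance",
    "auto_t_test",
    "star_annotation",
    "bonferroni",
]

_STAR_CUTS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class StatResult:
    """Outcome of a two-sample comparison.

    Attributes
    ----------
    test : {"pooled_t", "welch_t"}
        Which t-test the F-test gate selected.
    tails : int
        1 or 2.
    statistic, df, p_value : float
        t statistic, degrees of freedom, p-value.
    stars : str
        Figure-legend annotation ("" to "****").
    f_p_value : float
        p-value of the gating variance-ratio test.
    """

    test: Literal["pooled_t", "welch_t"]
    tails: int
    statistic: float
    df: float
    p_value: float
    stars: str
    f_p_value: float


def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise InsufficientReplicatesError(
            f"sample {name!r} needs n >= 2, got n={arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def f_test_equal_variance(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided variance-ratio F-test p-value.

    The larger sample variance goes in the numerator; the one-sided tail
    probability is doubled (capped at 1).

    Raises
    ------
    InsufficientReplicatesError
        If either sample has n < 2.
    ValueError
        If both samples have zero variance (the ratio is undefined).
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; F-test undefined")
    if va >= vb:
        num_v, num_df, den_v, den_df = va, a.size - 1, vb, b.size - 1
    else:
        num_v, num_df, den_v, den_df = vb, b.size - 1, va, a.size - 1
    if den_v == 0.0:
        return 0.0
    f = num_v / den_v
    p = 2.0 * sps.f.sf(f, num_df, den_df)
    return float(min(p, 1.0))


def auto_t_test(
    a: Sequence[float],
    b: Sequence[float],
    tails: int = 2,
    direction: Literal["greater", "less"] = "greater",
    alpha_var: float = 0.05,
) -> StatResult:
    """Two-sample t-test, pooled or Welch depending on a variance F-test.

    Parameters
    ----------
    a, b : sequences of float
        The two samples (a is the test arm, b the reference arm).
    tails : {1, 2}
        Two-tailed by default. One-tailed tests evaluate the alternative
        ``mean(a) > mean(b)`` (direction="greater") or ``<``.
    direction : {"greater", "less"}
        Hypothesized direction; only used when tails == 1.
    alpha_var : float
        Significance level of the gating F-test. Below it the Welch test
        (Welch-Satterthwaite df) is used, otherwise the pooled test.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    arr_a = _as_sample(a, "a")
    arr_b = _as_sample(b, "b")

    if arr_a.var(ddof=1) == 0.0 and arr_b.var(ddof=1) == 0.0:
        # Degenerate but well-defined comparison of two constants.
        f_p = 1.0
        equal_var = True
    else:
        f_p = f_test_equal_variance(arr_a, arr_b)
        equal_var = f_p >= alpha_var

    alternative = "two-sided" if tails == 2 else direction
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision warning; the t=0
        # result is what we want there
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(arr_a, arr_b, equal_var=equal_var, alternative=alternative)
    p = float(res.pvalue)
    if np.isnan(p):  # zero pooled variance, identical constants
        p = 1.0
        stat = 0.0
    else:
        stat = float(res.statistic)
    return StatResult(
        test="pooled_t" if equal_var else "welch_t",
        tails=tails,
        statistic=stat,
        df=float(res.df),
        p_value=p,
        stars=star_annotation(p),
        f_p_value=f_p,
    )


def star_annotation(p: float) -> str:
    """Map a p-value to the figure-legend star string.

    "****" if p < 1e-4, "***" if p < 1e-3, "**" if p < 0.01,
    "*" if p < 0.05, "" otherwise. Inequalities are strict.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    for cut, stars in _STAR_CUTS:
        if p < cut:
            return stars
    return ""


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (optional; not applied by default)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
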