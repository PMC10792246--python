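"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: the F-tail is obtained
by numerical integration of the density, and permutation p-values by exact
enumeration of all splits.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln


def f_sf_by_integration(f_obs: float, d1: int, d2: int) -> float:
    """Upper-tail F probability via numerical integration of the pdf."""

    def pdf(x: float) -> float:
        log_c = (
            gammaln((d1 + d2) / 2.0)
            - gammaln(d1 / 2.0)
            - gammaln(d2 / 2.0)
            + (d1 / 2.0) * np.log(d1 / d2)
        )
        return np.exp(
            log_c + (d1 / 2.0 - 1.0) * np.log(x) - ((d1 + d2) / 2.0) * np.log(1.0 + d1 * x / d2)
        )

    val, _ = quad(pdf, f_obs, np.inf, limit=200)
    return float(val)


def exact_permutation_p(
    a, b, tails: int = 2, mid_p: bool = True
) -> float:
    """Exact permutation p-value of the mean difference over all splits.

    ``mid_p=True`` returns the mid-p value (half weight on permutations
    tied with the observed statistic), the convention that matches the
    t-distribution most closely on tied small samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = len(a)
    idx = set(range(len(pooled)))
    obs = np.mean(a) - np.mean(b)
    if tails == 2:
        obs = abs(obs)
    ge = gt = total = 0
    for comb in combinations(range(len(pooled)), n):
        x = pooled[list(comb)]
        y = pooled[list(idx - set(comb))]
        d = np.mean(x) - np.mean(y)
        if tails == 2:
            d = abs(d)
        ge += d >= obs - 1e-12
        gt += d > obs + 1e-12
        total += 1
    if mid_p:
        return (ge + gt) / (2.0 * total)
    return ge / total
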