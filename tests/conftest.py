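"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: OLS by the
raw normal equations, and the Mann–Whitney null distribution by exhaustive
enumeration of rank assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest


def ols_normal_equations(x, y):
    """Brute-force OLS: slope, intercept, r², two-sided slope p-value.

    Solves the normal equations directly and computes the t-test from the
    residual sum of squares; independent of scipy.stats.linregress.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    ss_res = float((resid * resid).sum())
    ss_tot = float(((y - sy / n) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    se = math.sqrt(ss_res / (n - 2) / ((x - sx / n) ** 2).sum())
    from scipy.stats import t as tdist  # the t CDF itself is not under test

    tval = slope / se
    p = 2.0 * tdist.sf(abs(tval), n - 2)
    return slope, intercept, r2, p


def mann_whitney_exact_enumeration(a, b):
    """Exact two-sided Mann–Whitney p by enumerating all rank assignments.

    Only valid without ties; O(C(n+m, n)) so keep samples tiny.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"

    def u_of(indices_a):
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        r_a = sum(ranks[pooled[i]] for i in indices_a)
        n_a = len(indices_a)
        return r_a - n_a * (n_a + 1) / 2

    n = len(pooled)
    n_a = len(a)
    observed_a = [pooled.index(v) for v in a]
    u_obs = u_of(observed_a)
    mean_u = n_a * (n - n_a) / 2
    us = [u_of(c) for c in itertools.combinations(range(n), n_a)]
    # two-sided: arrangements at least as extreme (by distance from the mean)
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
    return u_obs, extreme / len(us)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
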