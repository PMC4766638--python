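"""Shared statistical primitives, vectorised over features.

These are thin closed-form layers over scipy's distribution functions so
that ten-thousand-feature calibration runs stay fast; the scientific
content (pooled two-sample t, two-sided Fisher's exact test) is standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

# Relative tie tolerance for the two-sided Fisher sum (tables whose
# probability is within this factor of the observed table's count as
# "as extreme"); same convention as scipy.stats.fisher_exact.
_FISHER_EPS = 1e-7


@dataclass
class TwoSampleT:
    """Elementwise results of a two-sample t-test across features."""

    diff: np.ndarray      # mean(a) - mean(b)
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    status: np.ndarray    # 'ok' | 'untested' | 'degenerate'


def two_sample_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> TwoSampleT:
    """Row-wise two-sample t-test between two (features × samples) arrays.

    NaNs are missing values.  The default is the Student pooled-variance
    test; ``welch=True`` switches to Welch's unequal-variance form.
    Rows with fewer than two observations in either group are 'untested'
    (all statistics NaN).  Rows with zero variance in both groups are
    'degenerate': p=1 (and diff forced to 0) when the group means agree,
    p=0 when they differ.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"):
        m_a = np.where(n_a > 0, np.nansum(a, axis=1) / np.maximum(n_a, 1), np.nan)
        m_b = np.where(n_b > 0, np.nansum(b, axis=1) / np.maximum(n_b, 1), np.nan)
        v_a = _nanvar(a, n_a)
        v_b = _nanvar(b, n_b)
    diff = m_a - m_b

    testable = (n_a >= 2) & (n_b >= 2)
    if welch:
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v_a / n_a + v_b / n_b
            df = se2**2 / (
                (v_a / n_a) ** 2 / (n_a - 1) + (v_b / n_b) ** 2 / (n_b - 1)
            )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((n_a - 1) * v_a + (n_b - 1) * v_b) / (n_a + n_b - 2)
            se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
            df = (n_a + n_b - 2).astype(float)

    degenerate = testable & (se2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * sps.t.sf(np.abs(t), df)

    status = np.where(testable, "ok", "untested").astype(object)
    status[degenerate] = "degenerate"
    equal_means = degenerate & (diff == 0)
    p = np.where(equal_means, 1.0, p)
    t = np.where(equal_means, 0.0, t)
    unequal = degenerate & (diff != 0)
    p = np.where(unequal, 0.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(unequal, np.sign(diff) * np.inf, t)
    p = np.where(testable, p, np.nan)
    t = np.where(testable, t, np.nan)
    diff = np.where(n_a * n_b > 0, diff, np.nan)
    return TwoSampleT(diff=diff, t=t, df=df, p=p, n_a=n_a, n_b=n_b, status=status)


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = np.full(x.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        out[ok] = np.nanvar(x[ok], axis=1, ddof=1)
    return out


_LGAMMA_CACHE = np.empty(0)


def _lgamma_table(n_max: int) -> np.ndarray:
    """gammaln(0..n_max+1) lookup, grown lazily (log-factorials)."""
    global _LGAMMA_CACHE
    if len(_LGAMMA_CACHE) < n_max + 2:
        _LGAMMA_CACHE = special.gammaln(np.arange(max(n_max + 2, 1024), dtype=float))
    return _LGAMMA_CACHE


def hypergeom_logpmf(k, n, K, N):
    """log P[X = k] for X ~ Hypergeom(N population, K successes, n draws).

    Integer arguments only; evaluated from a cached log-factorial table so
    large vectorised sweeps stay cheap.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    N = np.asarray(N, dtype=np.int64)
    lg = _lgamma_table(int(N.max()) if N.size else 0)
    return (
        _logcomb(K, k, lg)
        + _logcomb(N - K, n - k, lg)
        - _logcomb(N, n, lg)
    )


def _logcomb(n, k, lg):
    bad = (k < 0) | (k > n)
    kk = np.clip(k, 0, None)
    out = lg[n + 1] - lg[kk + 1] - lg[n - kk + 1]
    return np.where(bad, -np.inf, out)


def fisher_exact_two_sided(k, n, K, N):
    """Vectorised two-sided Fisher's exact p for 2×2 tables.

    Parameterised as a hypergeometric draw: population ``N``, of which
    ``K`` are marked; a sample of size ``n`` contains ``k`` marked items.
    p is the sum of the probabilities of all tables at least as extreme
    (probability ≤ observed, with a relative tie tolerance) — the same
    definition scipy uses.
    """
    k, n, K, N = np.broadcast_arrays(
        np.asarray(k, dtype=np.int64),
        np.asarray(n, dtype=np.int64),
        np.asarray(K, dtype=np.int64),
        np.asarray(N, dtype=np.int64),
    )
    shape = k.shape
    k, n, K, N = (x.ravel() for x in (k, n, K, N))
    if np.any((k < 0) | (k > n) | (k > K) | (n > N) | (K > N)):
        raise ValueError("inconsistent 2x2 table margins")
    jmin = np.maximum(0, n + K - N)
    jmax = np.minimum(n, K)
    log_obs = hypergeom_logpmf(k, n, K, N)
    threshold = log_obs + np.log1p(_FISHER_EPS)
    total = np.zeros(k.shape)
    for j in range(int(jmax.max()) + 1):
        valid = (j >= jmin) & (j <= jmax)
        if not valid.any():
            continue
        lp = hypergeom_logpmf(j, n, K, N)
        take = valid & (lp <= threshold)
        total[take] += np.exp(lp[take])
    p = np.minimum(total, 1.0)
    return p.reshape(shape) if shape else float(p[0])
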