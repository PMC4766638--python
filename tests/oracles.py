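"""Independent brute-force oracles used only by the tests.

Each oracle is deliberately written against the textbook definition with
primitives different from the implementation's (exact integer
combinatorics, numeric quadrature of the t density, exhaustive substring
enumeration), so agreement checks numerics rather than shared code.
"""

from __future__ import annotations

import math
from math import comb

from scipy.integrate import quad

# Same tie gate as the implementation (tables with probability within a
# 1e-7 relative factor of the observed one count as "as extreme"), so the
# comparison tests floating-point accuracy, not tie conventions.
FISHER_EPS = 1e-7


def fisher_two_sided_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact two-sided Fisher p by integer tail summation.

    Hypergeometric parameterisation: population N with K marked, sample
    of n contains k marked.
    """
    denom = comb(N, n)
    support = range(max(0, n + K - N), min(n, K) + 1)
    weights = {j: comb(K, j) * comb(N - K, n - j) for j in support}
    obs = weights[k]
    total = sum(w for w in weights.values() if w <= obs * (1 + FISHER_EPS))
    return total / denom


def pooled_t_p_oracle(x, y) -> float:
    """Two-tailed pooled-variance t-test p via quadrature of the t density."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))

    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(u):
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(pdf, abs(t), math.inf, epsabs=1e-15, epsrel=1e-13, limit=200)
    return 2 * tail


IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _parse_pattern(pattern: str) -> list[set[str]]:
    symbols = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            symbols.append(set(pattern[i + 1: j]))
            i = j + 1
        else:
            symbols.append(set(IUPAC_ORACLE[pattern[i]]))
            i += 1
    return symbols


def scan_oracle(sequence: str, pattern: str) -> list[int]:
    """Every substring tested per-symbol, on both strands."""
    symbols = _parse_pattern(pattern)
    rc = [set(_COMP[c] for c in s) for s in reversed(symbols)]
    m = len(symbols)
    out = []
    for i in range(len(sequence) - m + 1):
        window = sequence[i: i + m]
        if all(ch in sym for ch, sym in zip(window, symbols)) or all(
            ch in sym for ch, sym in zip(window, rc)
        ):
            out.append(i)
    return out


def bh_oracle(pvalues):
    """Benjamini–Hochberg step-up by the definition: q_(i) = min_{j>=i} p_(j) m/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q
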