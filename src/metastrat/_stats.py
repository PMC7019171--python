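"""Shared statistical primitives.

The one-sided enrichment p-value used both for cluster-vs-disease overlap
and pathway over-representation is computed here once, by exact integer
arithmetic, so both call sites agree to machine precision.
"""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts successes in a draw of ``n`` from a population of ``N``
    containing ``K`` successes.  Equivalent to a one-sided (greater)
    Fisher exact test on the corresponding 2x2 table.  Computed with exact
    integer binomials; the only rounding is the final float division.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid table: k={k}, K={K}, n={n}, N={N}")
    lo = max(k, 0, n + K - N)
    hi = min(K, n)
    if lo > hi:
        return 0.0 if k > 0 else 1.0
    numer = sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1))
    return numer / comb(N, n)


def rank_average(values: np.ndarray) -> np.ndarray:
    """Midranks (average rank for ties), 1-based."""
    from scipy.stats import rankdata

    return rankdata(values)
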