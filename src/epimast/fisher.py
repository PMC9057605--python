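"""Two-sided Fisher exact test on 2x2 tables.

The two-sided p-value follows the classical convention: sum the
hypergeometric probabilities of every table with the same margins whose
probability is less than or equal to that of the observed table, with a
relative tie tolerance of 1e-7 to remove floating-point ambiguity.

Small tables (grand total <= ``_EXACT_LIMIT``) are evaluated with exact
integer binomial coefficients; larger tables use log-gamma arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["fisher_exact", "FisherResult"]

_TIE_RTOL = 1e-7
_EXACT_LIMIT = 500


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # ad/bc; inf when bc==0 and ad>0; nan when 0/0
    p: float


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.nan if a * d == 0 else math.inf
    return (a * d) / (b * c)


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher exact test for ``[[a, b], [c, d]]``."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"table entries must be non-negative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        # a degenerate margin admits a single table
        return FisherResult(_odds_ratio(a, b, c, d), 1.0)

    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)

    if n_total <= _EXACT_LIMIT:
        weights = [math.comb(row1, int(x)) * math.comb(c + d, col1 - int(x)) for x in xs]
        w_obs = weights[a - lo]
        cutoff = w_obs + w_obs * _TIE_RTOL
        num = sum(w for w in weights if w <= cutoff)
        p = num / math.comb(n_total, col1)
    else:
        from scipy.special import gammaln

        log_denom = (
            gammaln(n_total + 1) - gammaln(col1 + 1) - gammaln(n_total - col1 + 1)
        )
        logw = (
            gammaln(row1 + 1) - gammaln(xs + 1) - gammaln(row1 - xs + 1)
            + gammaln(c + d + 1) - gammaln(col1 - xs + 1)
            - gammaln(c + d - col1 + xs + 1)
        )
        logp = logw - log_denom
        log_obs = logp[a - lo]
        keep = logp <= log_obs + math.log1p(_TIE_RTOL)
        p = float(np.exp(logp[keep]).sum())

    return FisherResult(_odds_ratio(a, b, c, d), min(1.0, float(p)))
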