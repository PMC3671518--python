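"""Audic-Claverie exact test for count differences between two libraries.

Given contig read counts ``x`` and ``y`` from two libraries with total
uniquely-mapped read counts ``N1`` and ``N2``, the Audic-Claverie model treats
``y`` conditional on ``x`` as negative-binomially distributed::

    p(y | x) = r**y * (x + y)! / (x! * y!) / (1 + r)**(x + y + 1),   r = N2 / N1

which is the negative-binomial mass with ``x + 1`` successes and success
probability ``N1 / (N1 + N2)`` evaluated at ``y``.  All evaluation is done in
log-space (log-gamma for the point mass, regularized incomplete beta for the
tails) so the functions stay finite for library-scale counts.

The two-sided p-value is the doubled one-sided tail in the direction of the
observed deviation of ``y`` from its conditional expectation ``x * N2 / N1``,
inclusive of the observed point and capped at 1 — conservative and symmetric
under exchanging the two libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonContext", "ACResult", "ac_point_prob", "ac_pvalue", "bh_adjust"]


@dataclass(frozen=True)
class ComparisonContext:
    """Totals of uniquely mapped reads for a two-library comparison.

    ``N1``/``N2`` are the library totals for sample one / sample two;
    ``label`` names the comparison (e.g. ``"BL_vs_BK"``).
    """

    N1: int
    N2: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError(
                f"library totals must be positive, got N1={self.N1}, N2={self.N2}"
            )


@dataclass(frozen=True)
class ACResult:
    """Per-contig test result: counts, point probability, p- and q-value."""

    x: int
    y: int
    point_prob: float
    p_value: float
    q_value: float = float("nan")


def _validate_counts(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("read counts must be non-negative")
    return x, y


def ac_point_prob(x, y, ctx: ComparisonContext):
    """Audic-Claverie point probability p(y | x).

    Vectorized over ``x`` and ``y``; returns a float for scalar input.
    """
    x, y = _validate_counts(x, y)
    log_r = np.log(ctx.N2) - np.log(ctx.N1)
    # log p = y log r + log C(x+y, y) - (x+y+1) log(1+r)
    log_p = (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(np.exp(log_r))
    )
    out = np.exp(log_p)
    return float(out) if out.ndim == 0 else out


def ac_pvalue(x, y, ctx: ComparisonContext):
    """Two-sided Audic-Claverie p-value (doubled inclusive tail, capped at 1).

    The lower tail P(Y <= y) and upper tail P(Y >= y) are evaluated through
    the regularized incomplete beta representation of the negative-binomial
    CDF, avoiding O(y) summation.
    """
    x, y = _validate_counts(x, y)
    p = ctx.N1 / (ctx.N1 + ctx.N2)
    lower = betainc(x + 1, y + 1, p)  # P(Y <= y)
    # P(Y >= y) = I_{1-p}(y, x+1) for y >= 1, else 1
    upper = np.where(y > 0, betainc(np.maximum(y, 1.0), x + 1, 1.0 - p), 1.0)
    pv = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(pv) if pv.ndim == 0 else pv


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; every adjusted value satisfies
    ``p <= q <= 1``.  Raises for p-values outside ``(0, 1]``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return np.maximum(q, p)  # guard against rounding below the raw p
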