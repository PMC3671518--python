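"""RPKM quantification, DEG calling, cross-comparison consistency, mapping rates.

A contig is called differentially expressed between two libraries when both
criteria hold: BH-adjusted Audic-Claverie q-value below ``q_threshold``
(default 1e-3) and an RPKM ratio of at least ``fc_threshold`` (default 2,
inclusive) in either direction.  "up" means higher in sample two of the
comparison; the study's belly-skin-reference orientation is obtained by
putting the reference library in the sample-one slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from anagen.actest import ComparisonContext, ac_pvalue, bh_adjust
from anagen.core import CountTable

__all__ = [
    "LibraryStats",
    "VennSummary",
    "compute_rpkm",
    "call_degs",
    "consistent_degs",
    "mapping_summary",
]


@dataclass(frozen=True)
class LibraryStats:
    """Raw / quality-filtered / uniquely-mapped read counts for one library."""

    library: str
    total_reads: int
    clean_reads: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.mapped_reads <= self.clean_reads <= self.total_reads):
            raise ValueError(
                f"{self.library}: require mapped <= clean <= total, got "
                f"{self.mapped_reads}/{self.clean_reads}/{self.total_reads}"
            )


@dataclass(frozen=True)
class VennSummary:
    """Cross-comparison consistency of two DEG call sets sharing a reference."""

    up_a: int
    down_a: int
    up_b: int
    down_b: int
    consistent_up: frozenset
    consistent_down: frozenset

    @property
    def n_consistent_up(self) -> int:
        return len(self.consistent_up)

    @property
    def n_consistent_down(self) -> int:
        return len(self.consistent_down)

    @property
    def total_consistent(self) -> int:
        return self.n_consistent_up + self.n_consistent_down


def compute_rpkm(counts: CountTable, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per contig per library.

    rpkm = 1e9 * C / (N_s * L) with N_s the library total and L the contig
    length in bp.  Returns a DataFrame aligned with the count matrix.
    """
    lengths = pd.Series(lengths)
    missing = counts.counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"no length for contigs: {list(missing[:5])} ...")
    L = lengths.loc[counts.counts.index].astype(float)
    if (L <= 0).any():
        raise ValueError("contig lengths must be positive")
    N = counts.totals.loc[counts.counts.columns].astype(float)
    if (N <= 0).any():
        raise ValueError("library totals must be positive")
    return 1e9 * counts.counts.div(N, axis=1).div(L, axis=0)


def call_degs(
    counts: CountTable,
    expression: pd.DataFrame,
    ctx: ComparisonContext,
    lib1: str,
    lib2: str,
    q_threshold: float = 1e-3,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Dual-threshold DEG calls for one pairwise comparison.

    Returns one row per contig with columns ``x, y, rpkm_1, rpkm_2,
    fold_change, p_value, q_value, direction, significant``.  The fold change
    used against the threshold is pseudocount-stabilized (one read added to
    both counts before forming the depth-normalized ratio) so presence/absence
    contigs get a finite, conservative ratio; reported RPKMs are raw.
    """
    if q_threshold <= 0 or fc_threshold < 1:
        raise ValueError("thresholds must satisfy q_threshold > 0, fc_threshold >= 1")
    if not counts.counts.index.equals(expression.index):
        raise ValueError("count table and expression table index contigs differently")
    x = counts.counts[lib1].to_numpy()
    y = counts.counts[lib2].to_numpy()
    p = ac_pvalue(x, y, ctx)
    # extreme count differences underflow to p = 0.0; clamp to the smallest
    # positive float so BH adjustment stays defined
    p = np.maximum(p, np.finfo(float).tiny)
    q = bh_adjust(p)
    # stabilized depth-normalized ratio; contig length cancels between libraries
    fc = ((y + 1.0) / ctx.N2) / ((x + 1.0) / ctx.N1)
    fold_ok = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    significant = (q < q_threshold) & fold_ok
    direction = np.where(~significant, "none", np.where(fc > 1.0, "up", "down"))
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "rpkm_1": expression[lib1].to_numpy(),
            "rpkm_2": expression[lib2].to_numpy(),
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": significant,
        },
        index=counts.counts.index.rename("contig_id"),
    )


def deg_sets(calls: pd.DataFrame) -> tuple[set, set]:
    """Ids of significant up- and down-regulated contigs from a call table."""
    up = set(calls.index[(calls["significant"]) & (calls["direction"] == "up")])
    down = set(calls.index[(calls["significant"]) & (calls["direction"] == "down")])
    return up, down


def consistent_degs(calls_a, calls_b) -> VennSummary:
    """Contigs consistently up / consistently down in two comparisons.

    Each argument is either a call table from :func:`call_degs` or an
    ``(up_ids, down_ids)`` pair.  Both comparisons must be oriented against
    the same reference sample (sample one); a contig listed both up and down
    within one comparison indicates an orientation mistake and raises.
    """

    def _sets(calls):
        if isinstance(calls, pd.DataFrame):
            return deg_sets(calls)
        up, down = calls
        return set(up), set(down)

    up_a, down_a = _sets(calls_a)
    up_b, down_b = _sets(calls_b)
    if up_a & down_a or up_b & down_b:
        raise ValueError("a contig cannot be both up and down within one comparison")
    return VennSummary(
        up_a=len(up_a),
        down_a=len(down_a),
        up_b=len(up_b),
        down_b=len(down_b),
        consistent_up=frozenset(up_a & up_b),
        consistent_down=frozenset(down_a & down_b),
    )


def mapping_summary(stats: list[LibraryStats]) -> pd.DataFrame:
    """Per-library mapped/clean percentage, rounded to one decimal for report."""
    rows = []
    for s in stats:
        if s.clean_reads == 0:
            raise ValueError(f"{s.library}: clean read count is zero")
        rate = 100.0 * s.mapped_reads / s.clean_reads
        rows.append(
            {
                "library": s.library,
                "total_reads": s.total_reads,
                "clean_reads": s.clean_reads,
                "mapped_reads": s.mapped_reads,
                "mapped_pct_of_clean": round(rate, 1),
            }
        )
    return pd.DataFrame(rows).set_index("library")
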