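"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContigRecord", "CountTable", "CdsRecord"]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled transcript contig."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"contig {self.id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CountTable:
    """Contigs x libraries matrix of uniquely-mapped read counts.

    ``counts`` is an integer DataFrame indexed by contig id with one column
    per library; ``totals`` holds each library's total uniquely-mapped reads
    N_s (column sums unless an external totals table is supplied, e.g. when
    some mapped reads fall on contigs outside the matrix).
    """

    counts: pd.DataFrame
    totals: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValueError("count table needs at least 2 library columns")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)
        self.totals = self.totals.astype(np.int64)
        missing = set(self.counts.columns) - set(self.totals.index)
        if missing:
            raise ValueError(f"totals missing for libraries: {sorted(missing)}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class CdsRecord:
    """A predicted coding sequence on a contig, 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    has_start_codon: bool = False
    has_stop_codon: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"CDS on {self.contig_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"CDS strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_full_length(self) -> bool:
        return self.has_start_codon and self.has_stop_codon
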