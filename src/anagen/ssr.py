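"""Perfect microsatellite (SSR) detection and summarization.

An SSR is a perfect tandem repeat of a primitive 2-6 bp motif whose full
copies span at least 18 bp.  Detection finds maximal period-k stretches with
a shifted self-comparison of the sequence, reports the left-aligned run of
full unit copies, and resolves overlapping candidates deterministically:
longest span first, left-most then shortest unit on ties.  N bases break
runs; partial trailing copies are excluded from the span and the copy count.

Motif classes group a motif with all its rotations and the rotations of its
reverse complement; the class representative (canonical motif) is the
lexicographic minimum, e.g. GT -> AC and CTG -> AGC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from anagen.core import ContigRecord

__all__ = ["SSRHit", "find_ssrs", "scan_contigs", "canonical_motif", "ssr_summary"]

DEFAULT_MIN_TOTAL_LEN = 18
DEFAULT_UNIT_RANGE = (2, 6)


@dataclass(frozen=True)
class SSRHit:
    """One perfect tandem repeat; 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    motif: str
    repeat_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repeat of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Class representative: minimum over rotations of motif and its reverse complement."""
    motif = motif.upper()
    if not (2 <= len(motif) <= 6) or not is_primitive(motif):
        raise ValueError(f"motif must be primitive and 2-6 bp, got {motif!r}")
    rc = reverse_complement(motif)
    rotations = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(rotations)


def _runs_of(mask: np.ndarray):
    """Yield (start, stop) half-open index ranges of consecutive True."""
    if not mask.any():
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def find_ssrs(
    sequence: str,
    min_total_len: int = DEFAULT_MIN_TOTAL_LEN,
    unit_range: tuple[int, int] = DEFAULT_UNIT_RANGE,
    contig_id: str = "",
) -> list[SSRHit]:
    """All SSRs of a sequence, non-overlapping, 1-based inclusive spans.

    Raises on characters outside A/C/G/T/N.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    valid = arr != b"N"

    candidates = []  # (span_len, start0, unit, motif, copies)
    lo, hi = unit_range
    for k in range(lo, hi + 1):
        if len(seq) < 2 * k:
            continue
        eq = (arr[k:] == arr[:-k]) & valid[k:] & valid[:-k]
        for s, e in _runs_of(eq):
            # seq[s : e + k] has period k and length (e - s) + k
            region_len = (e - s) + k
            copies = region_len // k
            if copies < 2 or copies * k < min_total_len:
                continue
            motif = seq[s : s + k]
            if not is_primitive(motif):
                continue  # caught by the scan at the primitive period
            candidates.append((copies * k, s, k, motif, copies))

    # longest span first; left-most, then shortest unit, on ties
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    hits: list[SSRHit] = []
    occupied: list[tuple[int, int]] = []
    for span_len, s, k, motif, copies in candidates:
        e = s + span_len - 1
        if any(s <= oe and e >= os_ for os_, oe in occupied):
            continue
        occupied.append((s, e))
        hits.append(
            SSRHit(
                contig_id=contig_id,
                start=s + 1,
                end=e + 1,
                motif=motif,
                repeat_count=copies,
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


def scan_contigs(
    contigs: Iterable[ContigRecord],
    min_total_len: int = DEFAULT_MIN_TOTAL_LEN,
    unit_range: tuple[int, int] = DEFAULT_UNIT_RANGE,
) -> list[SSRHit]:
    """Run :func:`find_ssrs` over a contig set."""
    hits = []
    for c in contigs:
        hits.extend(
            find_ssrs(c.sequence, min_total_len, unit_range, contig_id=c.id)
        )
    return hits


def occurrence_frequency(n_ssrs: int, n_contigs: int) -> float:
    """SSR occurrence frequency in percent: 100 * SSRs / contigs."""
    if n_contigs <= 0:
        raise ValueError("need a positive contig count")
    return 100.0 * n_ssrs / n_contigs


def mean_distance_bp(total_assembly_bp: float, n_ssrs: int) -> float:
    """Average assembly distance between SSRs in bp; NaN when there are none."""
    if n_ssrs == 0:
        return float("nan")
    return total_assembly_bp / n_ssrs


def ssr_summary(hits: Sequence[SSRHit], contigs: Sequence[ContigRecord]) -> dict:
    """Occurrence, density and motif-class composition of an SSR scan."""
    n_contigs = len(contigs)
    total_bp = sum(c.length for c in contigs)
    per_contig = Counter(h.contig_id for h in hits)
    unit_counts = Counter(len(h.motif) for h in hits)
    motif_counts = Counter(h.canonical for h in hits)
    n = len(hits)
    unit_names = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
    return {
        "total_ssrs": n,
        "total_contigs": n_contigs,
        "total_assembly_bp": total_bp,
        "contigs_with_ssr": len(per_contig),
        "contigs_with_2plus_ssrs": sum(1 for v in per_contig.values() if v >= 2),
        "occurrence_frequency_pct": occurrence_frequency(n, n_contigs),
        "mean_distance_bp": mean_distance_bp(total_bp, n),
        "unit_length_fractions": {
            unit_names.get(k, str(k)): unit_counts[k] / n for k in sorted(unit_counts)
        }
        if n
        else {},
        "motif_class_fractions": {m: c / n for m, c in motif_counts.most_common()}
        if n
        else {},
        "n_unique_motifs": len({h.motif for h in hits}),
    }
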