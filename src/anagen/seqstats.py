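"""Assembly and coding-sequence descriptive statistics.

Length-distribution bins follow the study's report table: 301-500, 501-700,
701-1000, 1001-1500, 1501-2000, >2000 bp (the printed "1500 ~ 2000" boundary
is resolved to 1501-2000 so the bins partition).  Codon usage is read in
frame from position 1 of each CDS, with amino-acid classes partitioned as
nonpolar (G,A,V,L,I,P,F,M,W,C), polar-uncharged (S,T,Y,N,Q), acidic (D,E)
and basic (K,R,H).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from anagen.core import CdsRecord

__all__ = [
    "DEFAULT_BIN_EDGES",
    "CodonUsageTable",
    "length_distribution",
    "n50",
    "gc_content",
    "extract_cds_sequence",
    "codon_usage",
    "stop_codon_frequencies",
    "cds_accounting",
]

# lower edges of the report bins; each bin spans [edge_i, edge_{i+1} - 1]
DEFAULT_BIN_EDGES = (301, 501, 701, 1001, 1501, 2001)

STOP_CODONS = ("TAA", "TAG", "TGA")

AA_CLASSES = {
    "nonpolar": set("GAVLIPFMWC"),
    "polar_uncharged": set("STYNQ"),
    "acidic": set("DE"),
    "basic": set("KRH"),
}

_CODON_TO_AA = dict(standard_dna_table.forward_table)


def length_distribution(
    lengths: Sequence[int], bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Contig counts and cumulative bp per report length bin.

    Bin *i* covers ``[bin_edges[i], bin_edges[i+1] - 1]``; the last bin is
    open-ended.  Lengths below the first edge are counted in the first bin so
    that counts always sum to the number of inputs.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size and (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    edges = list(bin_edges)
    labels = [
        f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f">{edges[-1] - 1}"]
    idx = np.clip(np.searchsorted(edges, lengths, side="right") - 1, 0, len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges)) if lengths.size else np.zeros(
        len(edges), dtype=np.int64
    )
    bp = (
        np.bincount(idx, weights=lengths, minlength=len(edges)).astype(np.int64)
        if lengths.size
        else np.zeros(len(edges), dtype=np.int64)
    )
    return pd.DataFrame(
        {"n_contigs": counts, "cumulative_bp": bp},
        index=pd.Index(labels, name="length_bin"),
    )


def n50(lengths: Sequence[int]) -> int:
    """Largest L with total length of contigs >= L at least half the assembly."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("N50 of an empty assembly is undefined")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    return int(desc[np.searchsorted(cum, cum[-1] / 2.0, side="left")])


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguous N bases are excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    c = Counter(sequence.upper())
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (c["G"] + c["C"]) / denom


def extract_cds_sequence(contig_seq: str, cds: CdsRecord) -> str:
    """CDS nucleotides in reading order (reverse-complemented for '-' strand)."""
    if cds.end > len(contig_seq):
        raise ValueError(
            f"CDS {cds.contig_id}:{cds.start}-{cds.end} exceeds contig length "
            f"{len(contig_seq)}"
        )
    sub = contig_seq[cds.start - 1 : cds.end].upper()
    return reverse_complement(sub) if cds.strand == "-" else sub


@dataclass
class CodonUsageTable:
    """Codon counts with amino-acid-class and stop-codon summaries."""

    codon_counts: Counter = field(default_factory=Counter)
    ambiguous_codons: int = 0
    gc_fraction: float = float("nan")

    @property
    def total_sense_codons(self) -> int:
        return sum(v for c, v in self.codon_counts.items() if c not in STOP_CODONS)

    @property
    def stop_counts(self) -> dict[str, int]:
        return {s: self.codon_counts.get(s, 0) for s in STOP_CODONS}

    @property
    def class_counts(self) -> dict[str, int]:
        out = dict.fromkeys(AA_CLASSES, 0)
        for codon, count in self.codon_counts.items():
            aa = _CODON_TO_AA.get(codon)
            if aa is None:
                continue
            for cls, members in AA_CLASSES.items():
                if aa in members:
                    out[cls] += count
                    break
        return out

    @property
    def class_fractions(self) -> dict[str, float]:
        total = self.total_sense_codons
        if total == 0:
            raise ValueError("no sense codons counted")
        return {cls: cnt / total for cls, cnt in self.class_counts.items()}


def codon_usage(cds_sequences: Iterable[str]) -> CodonUsageTable:
    """Codon counts over CDS sequences read in frame from position 1.

    Trailing 1-2 bases of a sequence are ignored; codons containing an
    ambiguous base are skipped and tallied as ambiguous.
    """
    counts: Counter = Counter()
    ambiguous = 0
    gc = at = 0
    for seq in cds_sequences:
        seq = seq.upper()
        if len(seq) < 3:
            raise ValueError("CDS sequences must be at least one codon long")
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if set(codon) <= {"A", "C", "G", "T"}:
                counts[codon] += 1
            else:
                ambiguous += 1
    gc_frac = gc / (gc + at) if (gc + at) else float("nan")
    return CodonUsageTable(codon_counts=counts, ambiguous_codons=ambiguous, gc_fraction=gc_frac)


def stop_codon_frequencies(
    cds_records: Sequence[CdsRecord], sequences: Mapping[str, str]
) -> pd.DataFrame:
    """Usage percentages of the three stop codons over stop-bearing CDSs.

    Only records flagged ``has_stop_codon`` are scanned; each contributes its
    terminal in-frame codon.  A terminal codon that is not TAA/TAG/TGA is a
    validation error naming the offending records.
    """
    tallies = Counter()
    offenders = []
    for cds in (r for r in cds_records if r.has_stop_codon):
        terminal = extract_cds_sequence(sequences[cds.contig_id], cds)[-3:]
        if terminal in STOP_CODONS:
            tallies[terminal] += 1
        else:
            offenders.append(f"{cds.contig_id}:{cds.start}-{cds.end} ends {terminal}")
    if offenders:
        raise ValueError(
            "CDS records flagged has_stop_codon do not end in a stop codon: "
            + "; ".join(offenders[:10])
        )
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("no stop-bearing CDS records supplied")
    return pd.DataFrame(
        {
            "count": [tallies[s] for s in STOP_CODONS],
            "percent": [round(100.0 * tallies[s] / total, 1) for s in STOP_CODONS],
        },
        index=pd.Index(STOP_CODONS, name="stop_codon"),
    )


def cds_accounting(cds_records: Sequence[CdsRecord]) -> dict:
    """Contig CDS-multiplicity and CDS-completeness accounting.

    Returns a dict with ``contigs_by_cds_count`` (multiplicity -> contigs),
    ``cds_by_completeness`` (full / start_only / stop_only / neither ->
    count), ``mean_length_by_completeness`` and the reconciling
    ``total_cds`` (= sum over multiplicities = sum over completeness
    classes).
    """
    per_contig = Counter(r.contig_id for r in cds_records)
    multiplicity = Counter(per_contig.values())

    def _class(r: CdsRecord) -> str:
        if r.has_start_codon and r.has_stop_codon:
            return "full"
        if r.has_start_codon:
            return "start_only"
        if r.has_stop_codon:
            return "stop_only"
        return "neither"

    by_class: dict[str, list[int]] = {
        "full": [], "start_only": [], "stop_only": [], "neither": []
    }
    for r in cds_records:
        by_class[_class(r)].append(r.length)
    return {
        "contigs_by_cds_count": dict(sorted(multiplicity.items())),
        "cds_by_completeness": {k: len(v) for k, v in by_class.items()},
        "mean_length_by_completeness": {
            k: (float(np.mean(v)) if v else float("nan")) for k, v in by_class.items()
        },
        "total_cds": len(cds_records),
        "total_contigs_with_cds": len(per_contig),
    }
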