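"""Readers and writers for the repository's canonical text formats.

FASTA is written uppercase at 70 columns.  Tables are tab-separated with
'#'-prefixed comment lines and a header row; count matrices put contig ids
in the first column followed by one integer column per library.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from anagen.core import CdsRecord, ContigRecord, CountTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_cds_table",
    "write_cds_table",
    "read_qpcr",
    "write_table",
]

FASTA_WIDTH = 70


def read_fasta(path) -> list[ContigRecord]:
    """Contig records from a FASTA file; ids must be unique, bases uppercased."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append(ContigRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(contigs: Iterable[ContigRecord], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), FASTA_WIDTH):
                fh.write(c.sequence[i : i + FASTA_WIDTH] + "\n")


def read_counts(path, totals_path=None) -> CountTable:
    """Count matrix from TSV (first column contig_id, one column per library).

    When ``totals_path`` (two columns: library, total) is given those values
    are used as library totals N_s; otherwise N_s = column sums.
    """
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            width = line.rstrip("\n").count("\t") + 1
            if n_fields is None:
                n_fields = width
            elif width != n_fields:
                raise ValueError(
                    f"{path}: line {lineno} has {width} fields, expected {n_fields}"
                )
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("count table needs a contig_id column and >=2 libraries")
    if df.iloc[:, 0].duplicated().any():
        dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
        raise ValueError(f"duplicate contig id in count table: {dup}")
    df = df.set_index(df.columns[0])
    df.index.name = "contig_id"
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any() or not (vals == vals.round()).all():
            raise ValueError(f"library {col}: counts must be non-negative integers")
    totals = None
    if totals_path is not None:
        t = pd.read_csv(totals_path, sep="\t", comment="#")
        totals = t.set_index(t.columns[0]).iloc[:, 0]
    return CountTable(df.astype("int64"), totals=totals)


def write_counts(table: CountTable, path, comments: Sequence[str] = ()) -> None:
    write_table(table.counts.reset_index(), path, comments)


def read_annotation(path) -> dict[str, set[str]]:
    """contig_id -> set of categories from a two-column TSV (comma-separated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    mapping: dict[str, set[str]] = {}
    for cid, cats in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if pd.isna(cats) or not str(cats).strip():
            continue
        mapping[cid] = {c.strip() for c in str(cats).split(",") if c.strip()}
    return mapping


def write_annotation(mapping: Mapping[str, Iterable[str]], path) -> None:
    rows = [
        {"contig_id": cid, "categories": ",".join(sorted(cats))}
        for cid, cats in sorted(mapping.items())
    ]
    write_table(pd.DataFrame(rows, columns=["contig_id", "categories"]), path)


def read_cds_table(path) -> list[CdsRecord]:
    """CDS records from TSV: contig_id, start, end, strand, has_start, has_stop."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig_id": str})
    return [
        CdsRecord(
            contig_id=str(r.contig_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            has_start_codon=bool(r.has_start),
            has_stop_codon=bool(r.has_stop),
        )
        for r in df.itertuples()
    ]


def write_cds_table(records: Sequence[CdsRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "contig_id": r.contig_id,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "has_start": int(r.has_start_codon),
                "has_stop": int(r.has_stop_codon),
            }
            for r in records
        ],
        columns=["contig_id", "start", "end", "strand", "has_start", "has_stop"],
    )
    write_table(df, path)


def read_qpcr(path) -> pd.DataFrame:
    """Ct table from TSV with columns gene, sample, replicate, ct."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "sample": str})
    required = {"gene", "sample", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    return df


def write_table(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    """TSV writer with '#'-prefixed header comments (e.g. threshold echoes)."""
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
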