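"""Microsatellite scan and codon-usage profile of the synthetic assembly.

The SSR scanner looks for perfect 2-6 bp tandem repeats spanning >= 18 bp
and is checked against the spans planted in step 01.  Codon usage is
demonstrated on synthetic coding sequences (random in-frame codons between a
start and a stop) embedded in the first contigs, since the study's CDS
predictions come from an external gene finder that is out of scope here.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from anagen import io as aio
from anagen.core import CdsRecord
from anagen.seqstats import codon_usage, extract_cds_sequence, stop_codon_frequencies
from anagen.ssr import scan_contigs, ssr_summary

IN = Path("results/synthetic")
OUT = Path("results/tables")


def synthetic_cds_records(contigs, n=300, seed=0):
    """Overlay synthetic in-frame CDS annotations on the first contigs."""
    rng = np.random.default_rng(seed)
    sense = [c for c in _SENSE_CODONS]
    records, seqs = [], {}
    for contig in contigs[:n]:
        n_codons = int(rng.integers(30, min(200, contig.length // 3 - 2)))
        body = "".join(rng.choice(sense, n_codons - 2))
        stop = str(rng.choice(["TAA", "TAG", "TGA"]))
        cds = "ATG" + body + stop
        seq = cds + contig.sequence[len(cds):]
        seqs[contig.id] = seq
        records.append(CdsRecord(contig.id, 1, len(cds), "+", True, True))
    return records, seqs


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    contigs = aio.read_fasta(IN / "contigs.fasta")
    truth = pd.read_csv(IN / "truth_ssr.tsv", sep="\t", comment="#")

    hits = scan_contigs(contigs)
    aio.write_table(
        pd.DataFrame(
            [
                {"contig_id": h.contig_id, "start": h.start, "end": h.end,
                 "motif": h.motif, "canonical_motif": h.canonical,
                 "repeats": h.repeat_count, "length": h.length}
                for h in hits
            ]
        ),
        OUT / "ssr_hits.tsv",
    )
    summary = ssr_summary(hits, contigs)
    with open(OUT / "ssr_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    planted = {
        tuple(r) for r in truth[["contig_id", "start", "end", "motif", "repeats"]]
        .itertuples(index=False)
    }
    found = {(h.contig_id, h.start, h.end, h.motif, h.repeat_count) for h in hits}
    print(
        f"{summary['total_ssrs']} SSRs in {summary['contigs_with_ssr']} contigs; "
        f"occurrence {summary['occurrence_frequency_pct']:.2f}%, "
        f"mean distance {summary['mean_distance_bp'] / 1000:.1f} kb; "
        f"planted recovery {len(planted & found)}/{len(planted)}"
    )

    records, seqs = synthetic_cds_records(contigs)
    usage = codon_usage([extract_cds_sequence(seqs[r.contig_id], r) for r in records])
    stops = stop_codon_frequencies(records, seqs)
    aio.write_table(stops.reset_index(), OUT / "stop_codon_usage.tsv")
    fractions = usage.class_fractions
    print(
        f"{len(records)} synthetic CDSs: "
        + ", ".join(f"{k} {100 * v:.1f}%" for k, v in fractions.items())
        + f"; CDS GC {100 * usage.gc_fraction:.1f}%"
    )
    print("stop codon usage:")
    print(stops.to_string())


if __name__ == "__main__":
    main()
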