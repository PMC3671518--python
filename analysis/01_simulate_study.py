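"""Generate the synthetic three-skin-library study used by every later step.

Writes the full input bundle (contig FASTA, count matrix, category
annotation, qPCR Ct table) plus the planted ground truth under
``results/synthetic/``.  Seed 0 throughout; rerunning reproduces the files
byte for byte.
"""

from pathlib import Path

import pandas as pd

from anagen import io as aio
from anagen.simulate import SimulationConfig, simulate_study

OUT = Path("results/synthetic")

CONFIG = SimulationConfig(
    n_contigs=5000,
    seed=0,
    ssr_plants=(
        ("AC", 9, 0), ("AGC", 7, 1), ("AAGT", 5, 2), ("AT", 15, 3),
        ("CCG", 8, 4), ("AACGTC", 3, 5),
    ),
)


def main() -> None:
    bundle = simulate_study(CONFIG)
    OUT.mkdir(parents=True, exist_ok=True)
    aio.write_fasta(bundle.contigs, OUT / "contigs.fasta")
    aio.write_counts(bundle.counts, OUT / "counts.tsv")
    aio.write_annotation(bundle.categories, OUT / "annotation.tsv")
    aio.write_table(bundle.qpcr, OUT / "qpcr_ct.tsv")
    truth = bundle.truth
    aio.write_table(
        pd.DataFrame(
            [
                {"contig_id": cid, "true_fold": fold,
                 "direction": "up" if fold > 1 else "down"}
                for cid, fold in sorted(truth.true_folds.items())
            ]
        ),
        OUT / "truth_de.tsv",
    )
    aio.write_table(
        pd.DataFrame(
            truth.ssr_spans,
            columns=["contig_id", "start", "end", "motif", "repeats"],
        ),
        OUT / "truth_ssr.tsv",
    )
    (OUT / "truth_enriched_category.txt").write_text(
        f"{truth.enriched_category}\n"
    )
    print(
        f"wrote {len(bundle.contigs)} contigs "
        f"({sum(c.length for c in bundle.contigs) / 1e6:.1f} Mb), "
        f"{len(truth.true_folds)} planted DE contigs "
        f"({len(truth.up_ids)} up, {len(truth.down_ids)} down), "
        f"{len(truth.ssr_spans)} planted SSRs, "
        f"{len(bundle.categories)} annotated contigs -> {OUT}/"
    )


if __name__ == "__main__":
    main()
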