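"""qPCR validation: 2^-ddCt fold changes vs the RNA-Seq fold changes.

Quantifies each assayed gene in the back- and side-skin samples relative to
the belly-skin calibrator, normalized by the reference gene, then scores
direction concordance against the RNA-Seq fold changes from step 03.
"""

from pathlib import Path

import pandas as pd

from anagen import io as aio
from anagen.qpcr import concordance, ddct_fold_change

IN = Path("results/synthetic")
OUT = Path("results/tables")
REFERENCE_GENE = "reference"
CALIBRATOR = "BL"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = aio.read_qpcr(IN / "qpcr_ct.tsv")
    genes = [g for g in dict.fromkeys(records["gene"]) if g != REFERENCE_GENE]
    samples = [s for s in dict.fromkeys(records["sample"]) if s != CALIBRATOR]

    rows = []
    qpcr_folds, rnaseq_folds = {}, {}
    for sample in samples:
        label = f"{CALIBRATOR}_vs_{sample}"
        deg = pd.read_csv(
            OUT / f"deg_{label}.tsv", sep="\t", comment="#", index_col=0
        )
        for gene in genes:
            fold = ddct_fold_change(records, gene, REFERENCE_GENE, sample, CALIBRATOR)
            qpcr_folds[(gene, label)] = fold
            rnaseq_folds[(gene, label)] = float(deg.loc[gene, "fold_change"])
            rows.append(
                {"gene": gene, "comparison": label, "qpcr_fold": round(fold, 3),
                 "rnaseq_fold": round(rnaseq_folds[(gene, label)], 3)}
            )
    table = pd.DataFrame(rows)
    aio.write_table(table, OUT / "qpcr_vs_rnaseq.tsv")
    result = concordance(qpcr_folds, rnaseq_folds)
    print(table.to_string(index=False))
    print(
        f"\ndirection concordance: {result.agreement:.2f} over {result.n} "
        f"gene/comparison pairs ({result.ties} tied at fold 1)"
    )


if __name__ == "__main__":
    main()
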