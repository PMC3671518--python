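"""Pairwise differential expression and cross-comparison consistency.

Runs the count test (q < 1e-3 after BH) with the two-fold RPKM criterion on
both comparisons against the belly-skin reference library, intersects the
calls into the consistent up/down sets, and scores them against the planted
truth from step 01.
"""

from pathlib import Path

import pandas as pd

from anagen import io as aio
from anagen.actest import ComparisonContext
from anagen.expression import call_degs, compute_rpkm, consistent_degs, deg_sets

IN = Path("results/synthetic")
OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    contigs = aio.read_fasta(IN / "contigs.fasta")
    lengths = pd.Series({c.id: c.length for c in contigs})
    counts = aio.read_counts(IN / "counts.tsv")
    truth = pd.read_csv(IN / "truth_de.tsv", sep="\t", index_col=0)
    rpkm = compute_rpkm(counts, lengths)

    calls = {}
    for other in ("BK", "BS"):
        label = f"BL_vs_{other}"
        ctx = ComparisonContext(
            int(counts.totals["BL"]), int(counts.totals[other]), label
        )
        table = call_degs(counts, rpkm, ctx, "BL", other)
        calls[label] = table
        aio.write_table(
            table.reset_index(), OUT / f"deg_{label}.tsv",
            ["q_threshold=0.001", "fc_threshold=2"],
        )
        up, down = deg_sets(table)
        print(f"{label}: {len(up)} up, {len(down)} down "
              f"of {len(table)} contigs")

    venn = consistent_degs(calls["BL_vs_BK"], calls["BL_vs_BS"])
    print(f"consistent across both comparisons: {venn.n_consistent_up} up, "
          f"{venn.n_consistent_down} down, {venn.total_consistent} total")

    true_up = set(truth.index[truth["direction"] == "up"])
    true_down = set(truth.index[truth["direction"] == "down"])
    hit = len(set(venn.consistent_up) & true_up) + len(
        set(venn.consistent_down) & true_down
    )
    false = len(set(venn.consistent_up) - true_up) + len(
        set(venn.consistent_down) - true_down
    )
    sens = hit / len(truth)
    fdp = false / max(1, venn.total_consistent)
    print(f"vs planted truth ({len(truth)} DE contigs): "
          f"sensitivity {sens:.3f}, false-discovery proportion {fdp:.4f}")

    consistent = pd.DataFrame(
        [{"contig_id": c, "direction": "up"} for c in sorted(venn.consistent_up)]
        + [{"contig_id": c, "direction": "down"} for c in sorted(venn.consistent_down)]
    )
    aio.write_table(consistent, OUT / "consistent_degs.tsv")


if __name__ == "__main__":
    main()
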