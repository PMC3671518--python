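"""Top-level pipeline: chain every analysis stage over files on disk."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from anagen import io as aio
from anagen.actest import ComparisonContext
from anagen.enrichment import enrich_categories
from anagen.expression import call_degs, compute_rpkm, consistent_degs, deg_sets
from anagen.qpcr import concordance, ddct_fold_change
from anagen.seqstats import (
    cds_accounting,
    codon_usage,
    extract_cds_sequence,
    gc_content,
    length_distribution,
    n50,
    stop_codon_frequencies,
)
from anagen.ssr import scan_contigs, ssr_summary

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("anagen")


@dataclass
class PipelineConfig:
    """Paths, comparisons and thresholds driving a full run."""

    fasta: str
    counts: str
    out_dir: str
    comparisons: list = field(default_factory=list)  # [ref_lib, other_lib] pairs
    annotation: str | None = None
    cds: str | None = None
    qpcr: str | None = None
    qpcr_reference_gene: str = "reference"
    totals: str | None = None
    q_threshold: float = 1e-3
    fc_threshold: float = 2.0
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate(self) -> None:
        if self.q_threshold <= 0 or self.fc_threshold < 1:
            raise ValueError("thresholds must satisfy q > 0 and fc >= 1")
        for key in ("fasta", "counts", "annotation", "cds", "qpcr", "totals"):
            p = getattr(self, key)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{key} file does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write TSV/JSON results.

    Stage order: RPKM -> per-pair Audic-Claverie + BH -> DEG calls -> Venn
    consistency -> enrichment -> assembly/CDS stats -> SSR scan -> qPCR
    concordance.  Reruns with identical config and inputs are byte-identical.
    Returns a dict of in-memory results keyed by stage.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = [
        f"q_threshold={config.q_threshold:g}",
        f"fc_threshold={config.fc_threshold:g}",
    ]
    results: dict = {}

    contigs = aio.read_fasta(config.fasta)
    lengths = pd.Series({c.id: c.length for c in contigs}, name="length")
    counts = aio.read_counts(config.counts, totals_path=config.totals)
    log.info("inputs: %d contigs, %d libraries", len(contigs), len(counts.libraries))

    rpkm = compute_rpkm(counts, lengths)
    aio.write_table(rpkm.round(4).reset_index(), out / "rpkm.tsv")
    results["rpkm"] = rpkm

    pairs = config.comparisons or [
        [counts.libraries[0], other] for other in counts.libraries[1:]
    ]
    calls = {}
    for ref, other in pairs:
        label = f"{ref}_vs_{other}"
        ctx = ComparisonContext(
            N1=int(counts.totals[ref]), N2=int(counts.totals[other]), label=label
        )
        table = call_degs(
            counts, rpkm, ctx, ref, other,
            q_threshold=config.q_threshold, fc_threshold=config.fc_threshold,
        )
        calls[label] = table
        aio.write_table(table.reset_index(), out / f"deg_{label}.tsv", thresholds)
        log.info("%s: %d significant of %d contigs", label, int(table["significant"].sum()), len(table))
    results["deg_calls"] = calls

    labels = list(calls)
    if len(labels) >= 2:
        venn = consistent_degs(calls[labels[0]], calls[labels[1]])
        aio.write_table(
            pd.DataFrame(
                [
                    {
                        "comparison_a": labels[0],
                        "comparison_b": labels[1],
                        "up_a": venn.up_a,
                        "down_a": venn.down_a,
                        "up_b": venn.up_b,
                        "down_b": venn.down_b,
                        "consistent_up": venn.n_consistent_up,
                        "consistent_down": venn.n_consistent_down,
                        "total_consistent": venn.total_consistent,
                    }
                ]
            ),
            out / "venn_summary.tsv",
            thresholds,
        )
        results["venn"] = venn

    if config.annotation is not None:
        annotation = aio.read_annotation(config.annotation)
        if "venn" in results:
            deg_ids = set(results["venn"].consistent_up) | set(
                results["venn"].consistent_down
            )
        else:
            up, down = deg_sets(calls[labels[0]])
            deg_ids = up | down
        enr = enrich_categories(
            deg_ids, annotation, set(counts.contig_ids), q_threshold=config.q_threshold
        )
        aio.write_table(enr.reset_index(), out / "enrichment.tsv", thresholds)
        results["enrichment"] = enr

    stats = {
        "n_contigs": len(contigs),
        "total_bp": int(lengths.sum()),
        "mean_length_bp": float(lengths.mean()),
        "n50_bp": n50(lengths.to_numpy()),
        "gc_fraction_contigs": gc_content("".join(c.sequence for c in contigs)),
    }
    ld = length_distribution(lengths.to_numpy())
    aio.write_table(ld.reset_index(), out / "length_distribution.tsv")
    if config.cds is not None:
        cds_records = aio.read_cds_table(config.cds)
        seqs = {c.id: c.sequence for c in contigs}
        stats["cds_accounting"] = cds_accounting(cds_records)
        cds_seqs = [extract_cds_sequence(seqs[r.contig_id], r) for r in cds_records]
        usage = codon_usage(cds_seqs)
        stats["codon_class_fractions"] = usage.class_fractions
        stats["gc_fraction_cds"] = usage.gc_fraction
        stop_bearing = [r for r in cds_records if r.has_stop_codon]
        if stop_bearing:
            stats["stop_codon_pct"] = (
                stop_codon_frequencies(stop_bearing, seqs)["percent"].to_dict()
            )
    with open(out / "assembly_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    results["stats"] = stats

    hits = scan_contigs(contigs)
    aio.write_table(
        pd.DataFrame(
            [
                {
                    "contig_id": h.contig_id,
                    "start": h.start,
                    "end": h.end,
                    "motif": h.motif,
                    "canonical_motif": h.canonical,
                    "repeats": h.repeat_count,
                    "length": h.length,
                }
                for h in hits
            ],
            columns=[
                "contig_id", "start", "end", "motif",
                "canonical_motif", "repeats", "length",
            ],
        ),
        out / "ssr_hits.tsv",
    )
    summary = ssr_summary(hits, contigs)
    with open(out / "ssr_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    results["ssr"] = summary

    if config.qpcr is not None:
        records = aio.read_qpcr(config.qpcr)
        ref_gene = config.qpcr_reference_gene
        samples = list(dict.fromkeys(records["sample"]))
        calibrator = samples[0]
        genes = [g for g in dict.fromkeys(records["gene"]) if g != ref_gene]
        qpcr_folds = {}
        pipeline_folds = {}
        for sample in samples[1:]:
            label = f"{calibrator}_vs_{sample}"
            table = calls.get(label)
            for gene in genes:
                qpcr_folds[(gene, label)] = ddct_fold_change(
                    records, gene, ref_gene, sample, calibrator
                )
                if table is not None and gene in table.index:
                    pipeline_folds[(gene, label)] = float(
                        table.loc[gene, "fold_change"]
                    )
        rows = [
            {
                "gene": g,
                "comparison": lab,
                "qpcr_fold": qpcr_folds[(g, lab)],
                "rnaseq_fold": pipeline_folds.get((g, lab), float("nan")),
            }
            for (g, lab) in sorted(qpcr_folds)
        ]
        aio.write_table(pd.DataFrame(rows), out / "qpcr_folds.tsv")
        if pipeline_folds:
            results["qpcr_concordance"] = concordance(qpcr_folds, pipeline_folds)

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "q_threshold": config.q_threshold,
                "fc_threshold": config.fc_threshold,
                "comparisons": [list(p) for p in pairs],
                "n_contigs": len(contigs),
                "libraries": counts.libraries,
                "library_totals": {k: int(v) for k, v in counts.totals.items()},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return results
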