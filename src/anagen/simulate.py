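"""Synthetic three-library skin RNA-Seq study with known ground truth.

Generates every input the pipeline consumes: contig FASTA sequences, a
contigs x libraries count matrix, a functional-category annotation table with
one planted enriched category, planted perfect SSRs, and qPCR Ct tables
consistent with the planted fold changes.

Default study conditions emulate the three-skin-type goat study scaled to
5,000 contigs: log-normal contig lengths (mean ~925 bp, minimum 301 bp),
GC fraction 0.549, three libraries (belly BL as reference, back BK, side BS)
whose depths are the study's mapped-read totals scaled to the contig count,
log-normal per-contig expression (wide dynamic range), a planted fraction of
contigs altered by a common fold in the non-reference libraries, and
Poisson counts (``dispersion > 0`` switches to gamma-mixed, i.e. negative
binomial, to probe overdispersion).

All generators are pure functions of (inputs, seed); identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from anagen.core import ContigRecord, CountTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_contigs",
    "plant_ssrs",
    "generate_count_matrix",
    "assign_categories",
    "generate_qpcr",
    "simulate_study",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the scaled study conditions."""

    n_contigs: int = 5000
    # log-normal length law: exp(mu + sigma^2/2) ~ 925 bp, floor at 301 bp
    length_log_mean: float = 6.55
    length_log_sd: float = 0.75
    min_length: int = 301
    gc_fraction: float = 0.549
    library_names: tuple[str, ...] = ("BL", "BK", "BS")
    # study mapped-read totals (35.6M / 34.0M / 42.4M) scaled to 5,000 contigs
    library_depths: tuple[float, ...] = (3_600_000.0, 3_450_000.0, 4_300_000.0)
    expression_log_sd: float = 1.5
    de_fraction: float = 0.15
    de_fold: float = 4.0
    dispersion: float = 0.0
    n_categories: int = 25
    enriched_category_effect: float = 8.0
    annotated_fraction: float = 0.36
    ssr_plants: tuple[tuple[str, int, int], ...] = ()  # (motif, copies, contig idx)
    n_qpcr_genes: int = 10
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 0:
            raise ValueError("n_contigs must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValueError("annotated_fraction must lie in [0, 1]")
        if self.de_fold < 1.0:
            raise ValueError("de_fold must be >= 1")
        if self.dispersion < 0.0:
            raise ValueError("dispersion must be >= 0")
        if len(self.library_depths) != len(self.library_names):
            raise ValueError("library_depths and library_names must align")
        if len(self.library_depths) < 2:
            raise ValueError("need at least 2 libraries")
        if any(d <= 0 for d in self.library_depths):
            raise ValueError("library depths must be positive")
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        if self.enriched_category_effect <= 0:
            raise ValueError("enriched_category_effect must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a simulated study."""

    up_ids: frozenset = frozenset()  # higher in every non-reference library
    down_ids: frozenset = frozenset()
    true_folds: dict = field(default_factory=dict)  # id -> fold in altered libraries
    comparisons: dict = field(default_factory=dict)  # label -> (up_ids, down_ids)
    ssr_spans: list = field(default_factory=list)  # (contig_id, start, end, motif, copies)
    enriched_category: str | None = None


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    contigs: list
    counts: CountTable
    truth: GroundTruth
    categories: dict  # contig_id -> set of category labels (annotated only)
    qpcr: pd.DataFrame

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(
            {c.id: c.length for c in self.contigs}, name="length"
        ).loc[[c.id for c in self.contigs]]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic substream per operation."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def generate_contigs(config: SimulationConfig) -> list[ContigRecord]:
    """Random contigs with log-normal lengths and the configured GC."""
    rng = _rng(config, 0)
    n = config.n_contigs
    if n == 0:
        return []
    lengths = np.maximum(
        config.min_length,
        np.round(rng.lognormal(config.length_log_mean, config.length_log_sd, n)),
    ).astype(np.int64)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    flat = rng.choice(_BASES, size=int(lengths.sum()), p=probs)
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    width = len(str(n))
    return [
        ContigRecord(
            id=f"contig_{i + 1:0{width}d}",
            sequence=flat[offsets[i] : offsets[i + 1]].tobytes().decode("ascii"),
        )
        for i in range(n)
    ]


def plant_ssrs(
    contigs: list[ContigRecord],
    ssr_plants: tuple[tuple[str, int, int], ...],
    seed: int,
) -> tuple[list[ContigRecord], list[tuple[str, int, int, str, int]]]:
    """Overwrite stretches of the given contigs with perfect tandem repeats.

    Each plant ``(motif, copies, contig_index)`` replaces ``copies *
    len(motif)`` bases at a random admissible position; total length is
    unchanged.  The single flanking base on each side is rewritten so the
    planted run cannot be extended by even a partial copy, making the
    recorded span exactly recoverable by the scanner.  Returns the modified
    contigs and the recorded 1-based inclusive spans.
    """
    out = {i: list(c.sequence) for i, c in enumerate(contigs)}
    spans: list[tuple[str, int, int, str, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    for motif, copies, idx in ssr_plants:
        motif = motif.upper()
        if idx >= len(contigs):
            raise IndexError(f"plant targets contig index {idx} of {len(contigs)}")
        plant = motif * copies
        L = len(out[idx])
        if len(plant) + 2 > L:
            raise ValueError(
                f"plant {motif}x{copies} ({len(plant)} bp) does not fit in "
                f"contig {contigs[idx].id} ({L} bp) with flanks"
            )
        taken = occupied.setdefault(idx, [])
        for _ in range(200):
            start = int(rng.integers(1, L - len(plant)))  # keep 1 bp flanks
            end = start + len(plant) - 1
            if all(end + 1 < s or start - 1 > e for s, e in taken):
                break
        else:
            raise ValueError(f"could not place plant {motif}x{copies} in contig {idx}")
        seq = out[idx]
        seq[start : end + 1] = list(plant)
        # break phase on both sides: left base != last motif base, right != first
        for pos, avoid in ((start - 1, motif[-1]), (end + 1, motif[0])):
            if 0 <= pos < L and seq[pos] == avoid:
                choices = [b for b in "ACGT" if b != avoid]
                seq[pos] = choices[int(rng.integers(0, 3))]
        taken.append((start, end))
        spans.append((contigs[idx].id, start + 1, end + 1, motif, copies))
    planted = [
        ContigRecord(id=c.id, sequence="".join(out[i])) if i in occupied else c
        for i, c in enumerate(contigs)
    ]
    return planted, spans


def generate_count_matrix(
    contigs: list[ContigRecord],
    config: SimulationConfig,
    counts_seed: int | None = None,
) -> tuple[CountTable, GroundTruth]:
    """Per-library read counts with a planted fraction of DE contigs.

    Per-contig expected counts are proportional to library depth x
    log-normal expression level x contig length (normalized over the
    baseline pool); a ``de_fraction`` of contigs is up- or down-regulated
    by ``de_fold`` in every non-reference library relative to the reference,
    with planting arranged to conserve each library's total expression (see
    the inline note).  Library totals are recorded as the realized column
    sums.  ``dispersion > 0`` mixes the Poisson mean with a
    Gamma(1/dispersion, dispersion) factor (negative binomial); 0 is plain
    Poisson.

    ``counts_seed`` redraws only the count noise while keeping expression
    levels and the planted DE assignment fixed — replicate draws of the
    same study for calibration work.
    """
    rng = _rng(config, 1)
    ids = [c.id for c in contigs]
    n = len(ids)
    if n == 0:
        raise ValueError("cannot build a count matrix from zero contigs")
    L = np.array([c.length for c in contigs], dtype=float)
    w = rng.lognormal(0.0, config.expression_log_sd, n)

    base = w * L
    share = base / base.sum()

    # Mass-balanced planting: up contigs are scaled by the fold in every
    # non-reference library, down contigs in the reference library (the same
    # relative change, placed so each library's total expression stays
    # matched).  Directions alternate greedily over decreasing expression
    # share so the two groups carry equal total output — the compositional
    # assumption implicit in normalizing by total mapped reads; without it
    # every null contig would inherit a spurious shift from the planted ones.
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    up_list, down_list = [], []
    mass_up = mass_down = 0.0
    for i in de_idx[np.argsort(-share[de_idx])]:
        if mass_up <= mass_down:
            up_list.append(i)
            mass_up += share[i]
        else:
            down_list.append(i)
            mass_down += share[i]
    fold_alt = np.ones(n)
    fold_alt[up_list] = config.de_fold
    fold_ref = np.ones(n)
    fold_ref[down_list] = config.de_fold

    count_rng = (
        rng
        if counts_seed is None
        else np.random.default_rng(np.random.SeedSequence(counts_seed, spawn_key=(201,)))
    )
    counts = {}
    for s, (name, depth) in enumerate(zip(config.library_names, config.library_depths)):
        f = fold_ref if s == 0 else fold_alt  # library 0 is the reference
        lam = depth * share * f
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = lam * count_rng.gamma(shape, 1.0 / shape, n)
        counts[name] = count_rng.poisson(lam)
    table = CountTable(pd.DataFrame(counts, index=pd.Index(ids, name="contig_id")))

    fold = fold_alt / fold_ref  # alt-vs-reference truth fold per contig
    up_ids = frozenset(ids[i] for i in up_list)
    down_ids = frozenset(ids[i] for i in down_list)
    ref = config.library_names[0]
    truth = GroundTruth(
        up_ids=up_ids,
        down_ids=down_ids,
        true_folds={ids[i]: float(fold[i]) for i in np.concatenate([up_list, down_list]).astype(int)} if n_de else {},
        comparisons={
            f"{ref}_vs_{name}": (up_ids, down_ids)
            for name in config.library_names[1:]
        },
    )
    return table, truth


def assign_categories(
    contigs: list[ContigRecord], config: SimulationConfig, truth: GroundTruth
) -> dict[str, set[str]]:
    """Functional-category labels with one planted enriched category.

    A fraction of contigs carries no annotation (and is absent from the
    returned mapping), mirroring a partially annotated transcriptome.  Every
    DE contig's odds of drawing the enriched category (the first label) are
    multiplied by ``enriched_category_effect``.  Updates
    ``truth.enriched_category`` in place and returns the mapping.
    """
    rng = _rng(config, 2)
    width = len(str(config.n_categories))
    labels = [f"KOG{i + 1:0{width}d}" for i in range(config.n_categories)]
    enriched = labels[0]
    de = truth.up_ids | truth.down_ids
    mapping: dict[str, set[str]] = {}
    annotated = rng.random(len(contigs)) < config.annotated_fraction
    for i, c in enumerate(contigs):
        if not annotated[i]:
            continue
        weights = np.ones(config.n_categories)
        if c.id in de:
            weights[0] *= config.enriched_category_effect
        weights /= weights.sum()
        mapping[c.id] = {labels[int(rng.choice(config.n_categories, p=weights))]}
    truth.enriched_category = enriched
    return mapping


def generate_qpcr(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Replicate Ct table consistent with the planted fold changes.

    For each selected DE gene, in every sample, Ct(target) - Ct(reference)
    equals -log2(fold in that sample) plus Gaussian noise of sd
    ``qpcr_noise_sd``; the reference gene's Ct is constant in expectation
    across samples.  Columns: gene, sample, replicate, ct.
    """
    if not truth.true_folds:
        raise ValueError("ground truth contains no fold changes")
    rng = _rng(config, 3)
    genes = sorted(truth.true_folds)[: config.n_qpcr_genes]
    samples = list(config.library_names)
    ref_gene = "reference"
    base_ct = 15.0
    rows = []
    for sample_idx, sample in enumerate(samples):
        for gene in [ref_gene] + genes:
            if gene == ref_gene:
                dct = 0.0
            else:
                f = truth.true_folds[gene] if sample_idx > 0 else 1.0
                dct = -np.log2(f)
            for rep in range(1, config.qpcr_replicates + 1):
                noise = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd else 0.0
                ct = base_ct + (dct if gene != ref_gene else 0.0) + noise
                rows.append({"gene": gene, "sample": sample, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


def simulate_study(config: SimulationConfig | None = None, **overrides) -> StudyBundle:
    """Generate a complete study: contigs, counts, truth, categories, qPCR."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    contigs = generate_contigs(config)
    contigs, spans = plant_ssrs(contigs, config.ssr_plants, config.seed)
    counts, truth = generate_count_matrix(contigs, config)
    truth.ssr_spans = spans
    categories = assign_categories(contigs, config, truth)
    if truth.true_folds:
        qpcr = generate_qpcr(truth, config)
    else:  # null study: nothing to validate by qPCR
        qpcr = pd.DataFrame(columns=["gene", "sample", "replicate", "ct"])
    return StudyBundle(
        config=config,
        contigs=contigs,
        counts=counts,
        truth=truth,
        categories=categories,
        qpcr=qpcr,
    )
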