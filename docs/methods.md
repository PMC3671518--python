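# Methods

## Count model and the Audic–Claverie test

The pipeline compares two RNA-Seq libraries with one observation per contig
per library: `x` uniquely-mapped reads in sample 1 (library total `N₁`) and
`y` in sample 2 (total `N₂`). Under the assumption that reads fall on a
contig as a Poisson process with a rate proportional to its (unknown)
expression, the conditional law of `y` given `x` after integrating the rate
out with a flat prior is negative binomial with `x+1` successes and success
probability `p = N₁/(N₁+N₂)`:

    p(y | x) = (N₂/N₁)^y · C(x+y, y) / (1 + N₂/N₁)^(x+y+1).

Evaluation is entirely in log space (log-gamma for the point mass); tails
use the regularized incomplete beta representation of the negative-binomial
CDF, `P(Y ≤ y) = I_p(x+1, y+1)`, so no O(y) summation is ever performed and
the functions are finite and accurate up to library-scale counts (tested at
x = y = 10⁶).

**Sidedness.** The two-sided p-value is `min(1, 2·min(P(Y ≤ y), P(Y ≥ y)))`
with both tails inclusive of the observed point — conservative, and the
natural two-sided form of a one-tailed exact test. One subtlety is
documented here because it is easy to assume otherwise: this construction
is *not* exactly invariant under exchanging the two samples. Swapping
`(x, N₁)` with `(y, N₂)` pairs an inclusive tail with an exclusive one, so
the two orientations can differ by up to one point mass per tail (for
`x=10, y=0, N₁=N₂` the two values are 2⁻¹⁰ and 2⁻⁹). The discrepancy is
bounded by the point masses and vanishes as counts grow; the test suite
asserts exactly that bound. Consequently a library swap flips every fold
change exactly but may flip a handful of borderline calls.

**Multiple testing.** Benjamini–Hochberg step-up over all contigs of a
comparison. p-values that underflow to exactly 0 at double precision
(extreme count differences) are clamped to the smallest positive float
before adjustment. Bonferroni is used for the enrichment stage (below),
matching the much smaller number of category tests.

## DEG calling

A contig is significant when both criteria hold: BH q < 10⁻³ and a fold
change ≥ 2 or ≤ ½ (both thresholds inclusive and configurable). The fold
change tested against the threshold is the depth-normalized count ratio
with one pseudo-read added to each side,
`((y+1)/N₂) / ((x+1)/N₁)` — contig length cancels between libraries, so
this equals the pseudocount-stabilized RPKM ratio. The pseudocount keeps
presence/absence contigs (zero in one library) usable without dividing by
zero while leaving all-zero contigs at ratio ≈ 1; reported RPKM values are
raw. "Up" always means higher in sample 2; putting the reference library
(belly skin in the motivating design) in slot 1 reproduces the
reference-oriented convention, and cross-comparison consistency is the
intersection of up sets and of down sets of two comparisons sharing that
reference.

## Enrichment

Category over-representation uses the hypergeometric upper tail
`P(X ≥ k)` with margins taken over the *annotated* universe only: `N`
annotated background contigs, `n` annotated DEGs, `K` background members of
the category, `k` DEG members. Unannotated contigs carry no information
about category membership and are excluded from both margins, mirroring
designs where fewer than half the contigs have any functional assignment.
The tail is an exact log-space sum (log-gamma + log-sum-exp); the suite
checks it against big-integer enumeration for every margin with N ≤ 25 and
against an independent distribution implementation on random margins.
Bonferroni q = min(1, p × number of categories tested); significance at
q < 10⁻³ by default.

## Sequence statistics

- **Length bins**: 301–500, 501–700, 701–1000, 1001–1500, 1501–2000,
  > 2000 bp. The source report's "1500 ~ 2000" row overlaps its neighbour;
  the bins here make a proper partition by assigning 1500 to the
  1001–1500 bin. Lengths below the first edge are counted in the first bin
  so totals always conserve.
- **N50**: the largest length L such that contigs ≥ L hold at least half
  the assembly; checked against an O(n²) oracle.
- **GC**: (G+C)/(A+C+G+T) with N excluded from the denominator. CDS GC and
  whole-contig GC are computed and labelled separately, since a report may
  mean either.
- **Codon usage**: read in frame from position 1 of each CDS (reverse
  strand handled by reverse complementation), trailing partial codons
  ignored, codons containing N tallied as ambiguous. Amino-acid classes use
  the standard partition — nonpolar G,A,V,L,I,P,F,M,W,C; polar-uncharged
  S,T,Y,N,Q; acidic D,E; basic K,R,H — over sense codons of the standard
  genetic code. Stop-codon usage scans the terminal in-frame triplet of
  stop-bearing CDSs and errors loudly on records whose terminal triplet is
  not TAA/TAG/TGA.

## SSR scanning

An SSR is a perfect tandem repeat of a primitive 2–6 bp motif whose full
copies span at least 18 bp. The scanner finds maximal period-k stretches by
comparing the sequence against itself shifted by k (N breaks runs), reports
the left-aligned run of full copies (partial trailing copies excluded from
span and count), keeps only primitive motifs (a (AT)ₙ run is a dinucleotide
hit, never a tetranucleotide one), and resolves overlapping candidates
deterministically — longest span first, left-most then shortest unit on
ties. Motif classes are the orbit under rotation and reverse complement,
represented by the lexicographic minimum (GT→AC, CTG→AGC). Equivalence with
a per-position regex oracle is asserted on 500 random kilobase sequences,
half drawn from a repeat-prone skewed alphabet.

Random synthetic contigs contain essentially no spontaneous ≥ 18 bp perfect
repeats, so SSR content in the synthetic study comes from explicit plants;
real transcriptomes are far more repeat-rich, and scanner behaviour on
realistic motif mixtures is what the oracle-equivalence property covers.

## qPCR

2^−ΔΔCt with technical replicates aggregated by arithmetic-mean Ct and
amplification efficiency fixed at 2 (the method's assumption; no standard-
curve correction). The normalizer gene is always a parameter. Concordance
between qPCR and RNA-Seq fold changes is the fraction of shared
(gene, comparison) pairs on the same side of 1, with folds exactly 1
counted as agreeing and reported separately as ties.

## Synthetic study generator

The generator emulates a three-library single-animal skin study scaled to
desk size, with every stream derived deterministically from one integer
seed (identical seeds give bit-identical outputs).

| knob | default | rationale |
|---|---|---|
| contigs | 5,000 | desk-scale stand-in for a ~50k-contig assembly |
| length law | log-normal, exp(6.55 + 0.75²/2) ≈ 925 bp, floor 301 bp | matches the motivating assembly's ~924 bp mean and 300 bp cutoff |
| GC | 0.549 | the assembly's reported GC |
| libraries | BL (reference), BK, BS | three skin regions, one library each |
| depths | 3.60 / 3.45 / 4.30 M reads | the study's mapped totals scaled to the contig count (~700 reads/contig/library) |
| expression | log-normal, σ = 1.5 (plus length) | reproduces a several-orders-of-magnitude dynamic range |
| DE fraction / fold | 0.15 / 4 | of the order of the study's DEG fraction; fold large enough to separate from noise |
| dispersion | 0 (Poisson) | the AC test's own model; > 0 gamma-mixes the mean (negative binomial) to probe overdispersion |
| categories | 25, one enriched (odds × 8), 36% annotated | 25 functional clusters; annotation coverage like real KOG assignment rates |
| qPCR | 3 replicates, Ct noise sd 0.1 | typical technical-replicate scatter |

**Mass-conserving DE planting.** Normalizing by total mapped reads assumes
the samples' total transcriptional output is comparable; if planted changes
all pointed one way, every null contig would inherit a spurious
compositional shift (at fold 8 and 15% DE, a naive 50/50 up/down plant
shifts the altered libraries' totals by ~46% and visibly mis-calibrates the
null). Planting therefore conserves output: up-regulated contigs are scaled
by the fold in the non-reference libraries, down-regulated contigs by the
same factor in the reference library (the identical relative change), and
directions are assigned by greedily balancing the two groups' summed
expression share, so each library's expected total stays matched to within
one contig's share. Up/down truth and per-contig fold (alt/reference) are
recorded exactly.

`generate_count_matrix` accepts an optional `counts_seed` that redraws only
the count noise while freezing expression levels and the planted DE
assignment — replicate draws of the same study, used by the calibration
tests.

Planted SSRs overwrite a random admissible stretch of the target contig and
additionally rewrite the single flanking base on each side so the repeat
cannot extend by a partial copy; the recorded span is then exactly what a
maximal-run scanner must report.

**What the generator does not emulate**: biological replication (none in
the motivating design), positional coverage bias, mappability and
multi-mapping artefacts, assembly errors, compound/interrupted SSRs,
annotation errors, or qPCR efficiency differences between genes. Passing
recovery tests therefore demonstrate correctness of the computations under
the model's own assumptions, not robustness to those real-data effects.

## Calibration and recovery study sizes

- Null type-I error: 10,000 contigs, two equal libraries of 5×10⁷ reads,
  Poisson, no DE. The deep libraries are deliberate: the AC test is a
  discrete exact test and is conservative at low per-contig counts, so its
  rejection rate approaches the nominal level only once typical counts are
  in the thousands (the totals match the study's ~40–50 M clean reads per
  library). The observed rate is checked against the 99% binomial band at
  α = 0.05 and 0.01.
- Parameter recovery: 5,000 contigs, fold 8, two 2×10⁶-read libraries;
  sensitivity ≥ 0.9 and false-discovery proportion ≤ 0.05 among calls
  (measured ≈ 0.99 and ≈ 0).
- Oracle equivalences: enrichment vs enumeration for all N ≤ 25; SSR vs
  regex on 500 random kb; N50/binning vs quadratic oracles.

## Known limitations

- Single-library-per-condition designs cannot separate biological
  variability from expression differences; the AC test treats all
  overdispersion as signal. The generator's `dispersion` knob exists
  precisely to probe how quickly calls inflate under negative-binomial
  noise.
- Per-total normalization (RPKM) carries composition bias when a large
  expression mass changes in one direction; the pipeline implements the
  method as specified and the generator documents the assumption rather
  than correcting for it (TMM-style normalization is out of scope).
- The inclusive-tail p-value's sample-order asymmetry (bounded by the point
  mass) is documented above.
- Compound and interrupted SSRs are not detected, and mononucleotide runs
  are excluded by the 2–6 bp unit definition.
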