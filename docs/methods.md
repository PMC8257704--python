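# Methods

## The question being operationalized

m6A methylation is deposited within a degenerate consensus, RRACH, whose
strongest form is GGACH (R = purine, H = not-G; the A is the methylated
position). miRNAs repress targets through Watson–Crick pairing of their seed
(mature positions 2–8) with 3'UTR sites. When the m6A consensus lies inside
a seed-complementary site, the same adenosine can be both methylated and
seed-paired, so methylation state can modulate that particular miRNA's
repression. The pipeline asks four nested questions: which miRNA seeds are
inversely complementary to the consensus; which target genes carry both a
seed site and an m6A mark; whether m6A-modified targets show higher
RISC/AGO2 enrichment; and whether they are preferentially down-regulated
across stages.

## Seed–motif screen

The seed is the 1-based inclusive span (2, 8) of the mature strand by
default (configurable; position 1 is excluded from pairing by convention).
Its reverse complement is the mRNA-strand site sequence. "Inversely
complementary to the motif" is operationalized as *containment*: the 5-nt
motif occurs as a contiguous window at one of the three possible offsets
inside the 7-nt site sequence. A 5-mer cannot equal a 7-mer, so containment
is the only consistent reading of the alignment. Both motif tiers are
scanned in one pass; FULL (stringent hit) implies the relaxed condition
because every GGACH match is an RRACH match.

## Motif scanning semantics

Sequences are normalized to RNA (T→U, upper case); coordinates are 0-based
half-open everywhere internally (BED-compatible). All overlapping hits are
reported. Ambiguity codes in a scanned *sequence* match nothing by default —
a conservative choice so that an N never manufactures a motif hit — with an
opt-in flag that lets N match any motif position.

## Target sites

The canonical site taxonomy is used: 6mer = UTR match to the reverse
complement of seed positions 2–7; 7mer-m8 adds position 8; 7mer-A1 adds an
adenosine in the UTR opposite miRNA position 1 (the base immediately 3' of
the seed-paired region, an Argonaute-recognized A rather than a paired
base); 8mer has both. Reported intervals cover the seed-paired region only
(6 or 7 nt); the A1 adenosine is checked at offset `end` but not included,
so the interval is exactly reverse-complementary to the seed positions the
type requires. Each core-match locus is reported once with its strongest
type. The default minimum type is 7mer-m8, matching the 7-nt seed span used
in the screen. Site finding uses fixed canonical positions 2–8 regardless of
the screen's configurable span, since the taxonomy is defined on those
positions.

## m6A status of a gene

Default rule: m6A-modified target = has site AND in the m6A-RIP gene set
AND GGACH present in the supplied UTR sequence — a two-step filter
(experimentally derived gene set, then motif presence) composed with target
status. A stricter variant additionally requires a motif hit to intersect a
site interval (half-open intersection), for analyses where the mark must sit
in the binding site itself. The package scans whatever sequence the caller
supplies as "the UTR"; if the region of interest includes the stop-codon
vicinity, include it in the FASTA — the caller defines the region.

## Overlap and score comparison

Overlap percentages are exact rational arithmetic (`fractions.Fraction`)
rendered half-up at two decimals, so printed values like 30.20% (270/894)
and 24.52% (102/416) are reproduced digit-for-digit rather than through
floating-point rounding. The score comparison is the unpaired two-tailed
two-sample t test; the default is the classical pooled-variance Student
variant (df = n1+n2−2), with Welch available because real enrichment scores
are heteroscedastic. One score per gene is assumed; genes scored but not
annotated, or annotated but unscored, are logged and excluded from the
comparison only (not from the overlap). If every value in both groups is
identical the statistic is defined as t = 0, p = 1; zero pooled variance
with differing means cannot arise. No multiple-testing correction is
applied: each figure-level contrast is a single planned comparison, and the
report says so rather than silently adjusting.

## Stage dynamics

Per gene, log2((v_cmp + pseudocount)/(v_ref + pseudocount)); DOWN/UP at a
symmetric threshold, default fold-change 1.5 with pseudocount 0. The 1.5
default is a conventional proteomics cutoff; because direction-count
summaries in the literature rarely state their cutoff, a sensitivity table
at 1.2/1.5/2.0 is always available, and fc_threshold = 1.0 gives sign-only
calls. A zero reference value with pseudocount 0 is per-gene not-computable
(logged, excluded from counts); a zero comparison value is an unbounded
decrease (DOWN). Stratified percentages use down/(down+up), excluding
UNCHANGED, matching the two-category rendering of developmental summaries.
Multi-stage trajectories are repeated pairwise calls against the reference
stage; the pressure-overload (Sham vs TAC) design is the same machinery with
UP as the highlighted category.

## Synthetic data

The generator's defaults are the study conditions the pipeline is designed
around: 139 catalogue miRNAs with 1 stringent and 9 relaxed-only planted
seed matches; P(target) = 0.30 and P(m6A | target) = 0.302; a +1.0 score
shift at sd 1.0; and two-stage dynamics with planted down-regulation
probabilities 0.862 (m6A-modified targets) vs 0.723 (all other genes) at a
2-fold magnitude. UTR lengths are Poisson around 200 nt (minimum 60);
base composition is uniform — no GC or dinucleotide bias model is imposed.

Construction is plant-then-verify: background sequence is drawn uniformly,
the site and/or motif instance spliced in, boundary bases adjusted so the
planted site type is exact (no chance A1 promotion or m8 extension), and the
final sequence verified with the pipeline's own primitives — exactly one
site of the planted type, and GGACH present exactly where expected — with
whole-gene rejection and retry otherwise. This makes the discrete truth
*exact*: the alternative of tolerating accidental background hits would turn
recovery tests into probabilistic ones. A consequence worth knowing: a
miR-133a-like site sequence (GGACCAA) inherently contains a GGACH instance,
so every target of such a miRNA has the motif in its UTR by construction;
the truth table accounts for this analytically.

Scores are Normal and reference abundances lognormal (σ = 0.5 around a
median of 100); later stages scale each gene deterministically by
fold ±2.0, so regulation calls recover the planted Bernoulli draws exactly
whenever the fold magnitude exceeds the calling threshold. All randomness
flows through one `numpy.random.default_rng` (PCG64) stream seeded from the
config, giving byte-identical files per seed.

What the generator does **not** emulate: read-level data (no FASTQ or
RIP-seq reads, no peak calling), sequence composition bias, isoform or UTR
annotation ambiguity, correlated scores between genes, replicate-level
measurement noise in the stage matrix, and partial overlap between the
universes of the different assays (every gene has a UTR, a score if
targeted, and abundance values). Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated
assumptions, not robustness to the messiness of real libraries.

## Problem sizes and numerical choices

Recovery and round-trip demonstrations use 139-miRNA catalogues and genomes
of 150–2,000 genes — sizes chosen so the discrete strata are large enough
for binomial confidence checks while the full suite runs in seconds.
Percentages are half-up at two decimals; t statistics and p-values are
IEEE doubles straight from `scipy.stats`; interval logic is half-open
throughout, so zero-length intersections cannot occur. Duplicate miRNA
names, duplicate gene ids, empty sequences and invalid IUPAC codes are
rejected at construction with messages naming the offender.

## Known limitations

No thermodynamic duplex scoring, conservation filtering, or context-style
efficacy modeling — target calls are purely seed-match. No
differential-expression modeling (no variance shrinkage or replicate-aware
testing): stage summaries are direction counts, which is what they are
meant to be. The overlap report gives raw percentages without a
hypergeometric enrichment p-value. Genome-to-transcript coordinate lifting
is out of scope: peak intervals are interpreted in the coordinate space of
the supplied UTR sequences.
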