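# Methods

This note documents the models, parameter choices and numerical decisions
behind `polvtx`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and formats

All coordinates are 0-based half-open internally (BED convention); GFF3 is
converted on read (1-based inclusive → internal) and cytosine-report
positions likewise. Strand is `+`/`-`/`.`. Region overlap everywhere means
≥ 1 bp of shared sequence, matching the default semantics of the standard
interval tools; an interval's "center" is `floor((start+end)/2)`. Signed
TSS distances are negative when the query center lies upstream of the TSS
in the gene's own orientation, so "−400 bp" always means 400 bp before the
gene regardless of strand. Writers emit deterministic ordering (genome
chromosome order, then start), which is what makes whole-run manifests
byte-reproducible.

## Coverage and correlation

`coverage_track` computes per-bin mean per-base depth. RPGC ("1×")
normalization multiplies raw depth by
`effective_genome_size / (total reads × mean read length)` with mean read
length defined as total aligned bases / read count, so the scale factor is
`effective_genome_size / total aligned bases` and the genome-wide weighted
mean coverage equals 1 when the effective size equals the genome size
(asserted to 1e-9 in tests). Track correlation is Pearson over bins,
optionally restricted to bins overlapping a region set; the log transform
is `log2(x + 1)` — the +1 pseudocount keeps the many zero bins finite and
is the only free choice in that operation.

## Binarization

The per-mark enrichment call is a Poisson upper-tail test against the
genome-wide mean bin count λ̂: a bin with count c is enriched iff
`P(X ≥ round(c)) < 10⁻⁴` for `X ~ Poisson(λ̂)`. This is closed-form,
deterministic and testable against direct pmf summation. It presumes a
background-dominated genome: if a large fraction of bins is enriched, λ̂
is inflated, the threshold count rises, and truly enriched bins start
failing the test. The 10⁻⁴ threshold is exposed (`--pthresh`).

## The co-occupancy HMM

States emit marks as independent Bernoulli draws given the state
(`E[k,m]` = probability mark m is enriched in state k); chromosomes are
independent chains restarted from the initial distribution π. The number
of states defaults to K = 6 — background, NRPE1-only, NRPE1–SPT6L shared,
two genic SPT6L configurations, Pol II — but is a free parameter; no model
selection across K is attempted.

Fitting is Baum–Welch EM with a scaled forward–backward pass (a numba
kernel with an equivalent numpy fallback). Defaults: `max_iter` 200,
`tol` 1e-4 log-likelihood units, best of `n_init` = 5 restarts. Restart 0
initializes emissions from the K most frequent observed mark patterns
(softened to 0.1/0.9) — with ≤ 2^M distinct observables this lands near
the dominant mode and converges in tens of iterations; the remaining
restarts draw emissions uniform(0.1, 0.9) from seeds `seed+1 …`. The
restart with the highest final log-likelihood wins. EM on binarized
multi-mark data is genuinely multimodal (rare states merge, background
splits), which is why a single random start is not the default. The
per-iteration log-likelihood trace is retained and asserted non-decreasing
(tolerance 1e-8 for arithmetic noise). Emission logs are clipped at
1e-300, so degenerate 0/1 emissions decode exactly.

Decoding is posterior-maximal per bin (forward–backward), matching
per-bin state counting; Viterbi is available by flag. State labels are a
deterministic rule on emission rows at threshold τ = 0.5: no mark high →
background; NRPE1 alone → NRPE1-only; NRPE1+SPT6L without Pol II →
NRPE1–SPT6L shared; SPT6L+Pol II → genic SPT6L; anything else is named by
its high-mark set. τ = 0.5 cleanly separates enriched from background in
well-separated fits; it is not meaningful when emissions are diffuse.

`nearest_downstream_tss` assigns each region the gene whose TSS lies
ahead of the region center in the gene's own orientation, nearest first,
ties broken by lexicographic gene id; regions with no downstream gene are
reported unassigned.

## RIP-seq transcript calling

Stage order: UMI extraction (8 bp prefix appended to the read id after an
underscore) → trimming (one leading `TATAGGG` occurrence, allowing one
mismatch by default since sequencing errors in a 7-mer tag are common —
exact matching by flag; then the maximal trailing run of ≥ 3 A's with at
most one non-A interruption; discard below 10 nt) → external alignment →
UMI deduplication on (chromosome, strand-aware 5′-end coordinate, strand,
UMI), keeping the first read in input order → background subtraction
(strand-aware ≥ 1 bp overlap with any control read removes the IP read;
strand-blind mode by flag) → peak assignment (any overlap retains; a read
spanning several peaks is counted once in the transcript total and once
per overlapped peak, preserving both marginal totals). Every stage
reports counters that sum to the stage input.

Abundance is reads per million, with the library total defined as the
deduplicated aligned read count of the sample — this includes reads
outside peaks, which is what lets a genuine loss of Pol V transcripts show
up after library-size normalization. The rank-sum comparison uses the
exact null when `min(n) ≤ 10` with no ties and the normal approximation
with tie and continuity correction otherwise; identical samples return
p = 1 by construction.

## U-10 slicing statistic

U is counted as T in DNA-space sequences, which must be in transcript
orientation (the readers enforce reverse-complementation for minus-strand
reads). Reads shorter than the position (10) are excluded from numerator
and denominator. The low-coverage exclusion requires ≥ 10 reads in *both*
the reference (GRO-seq-like) and the query (RIP) set — a ratio from fewer
than 10 reads is unstable whichever role it plays; `--filter-mode any`
keeps peaks reaching 10 in at least one set. Grouping is equal-size
quantile groups (4 by default) on the reference ratio, ties broken by
peak id, so output is deterministic.

The shuffle null repositions every read uniformly at random inside its
peak, preserving length and strand, and re-extracts the sequence from the
genome — the null therefore reflects local base composition, and its
expected ratio equals the peak's eligible-position T frequency (verified
within 3 standard errors). Reads longer than their peak are kept in place
and counted as unshufflable. Three shuffles are averaged per peak.

## DMR calling

Windows tile from position 0 of each chromosome (500 bp, step 500 ⇒
non-overlapping; a sliding step must divide the window). Cytosines with
coverage < 4 are excluded before pooling; windows with no covered cytosine
in a sample are absent, and windows present in only one sample are skipped
and reported. The per-window test is a two-sided Fisher exact test on the
pooled (methylated/unmethylated × sample) table — the appropriate exact
test when replicates are pooled; a replicate-aware regression mode is a
possible future extension. Multiple testing is Benjamini–Hochberg within
each context (contexts are tested separately; a window can be a DMR in one
context only). A DMR requires both `q < 0.01` and an absolute level
difference ≥ 25 percentage points, so no coverage depth can push a
sub-threshold difference into the call set. "hypo" means the test
(mutant) sample is below the reference.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs at
desk scale; defaults are chosen so the full pipeline runs in well under a
minute of generation time: a 2-Mb genome (two 1-Mb chromosomes, GC 0.36 as
in Arabidopsis), 200 genes, 300 peaks, ≈ 20k IP reads per RIP sample plus
6k genome-wide background reads, and a chromosome-1 methylome (≈ 360k
cytosines at ≈ 20× coverage). One global seed spawns independent
per-component generator streams (genome, ChIP, RIP, methylome), so
regenerating one component does not shift the others, and all outputs are
byte-identical for a fixed configuration.

*ChIP*: the true state path is Markov over 200-bp bins with a
background-dominated transition structure (background self-transition
0.99; enriched states persist at 0.85 and mostly return to background),
giving ≈ 93% background occupancy; per-bin counts are Poisson with rate 20
(enriched) or 1 (background) per mark. The TSS-distance structure is
planted by overriding the drawn state near gene TSSs — alternate genes
carry an NRPE1-only bin 200 bp upstream (proximal) or a shared
NRPE1+SPT6L bin 400 bp upstream (distal). Planting one band per gene
keeps the path locally consistent with a Markov model; planting both at
the same gene creates adjacent forced state pairs that the maximum-
likelihood HMM explains by blending emissions, which is a property of the
conditioning, not of the fitter.

*RIP*: per peak, read counts are Poisson (wild type 60, mutant 30 — the
planted abundance effect), lengths normal (means 60 vs 45 nt, sd 15 — the
planted elongation effect), strands random. A per-group fraction of reads
(0.05/0.15/0.25/0.40) is "sliced": the start is drawn uniformly among the
in-peak positions that put a T at read position 10, so the planted U-10
ratio is fraction + (1 − fraction) × background T frequency. Raw FASTQ
records are UMI + `TATAGGG` + insert + poly(A); PCR duplicates are
injected at rate 0.1; the control sample is sparse genome-wide background.

*Methylome*: cytosines and contexts are derived from the genome sequence
on both strands; baselines CG 0.8, CHG 0.4, CHH 0.1; coverage Poisson(20);
methylated counts binomial. Forty 500-bp windows (cycling contexts) shift
the test sample by 40 pp in whichever direction stays inside (0, 1) —
hypo for CG, hyper for CHG/CHH at the default baselines.

**What the generator does not model**: sequencing errors and quality
scores, mapping ambiguity, bisulfite conversion failure, biological
replicate variance (methylation levels are exact binomials around a flat
baseline), transposon family structure, and chromatin-state autocorrelation
beyond first-order Markov. Passing tests therefore demonstrate the
correctness of the computations under their stated models, not robustness
to the full noise structure of real libraries.

## Problem sizes in the test and acceptance runs

Unit tests run a reduced bundle (two 300-kb chromosomes, 60 peaks); the
acceptance suite and `scripts/acceptance.py` use the full default scale
(2-Mb genome, 10,000 bins, 300 peaks, 6000 DMR windows) and verify the
exact oracles on: all 2×2 tables with total ≤ 60 (Fisher, on symmetry-orbit
representatives), all state paths for K ≤ 3, T ≤ 8 (forward likelihood),
full permutation enumeration for rank-sum samples up to n = 6, and Poisson
tail sums for counts 0–50.

## Known limitations

- The HMM assumes conditionally independent marks given the state;
  correlated assay noise would be absorbed into extra states.
- Quantile peak grouping by an observed reference ratio regresses group
  means toward the grand mean relative to the planted fractions
  (selection on noise); comparisons across samples within a group are
  unaffected.
- Fisher on pooled replicates treats biological replicates as one
  library and can be anticonservative under true replicate dispersion.
- The binarization threshold is calibrated against the genome-wide mean;
  strong copy-number or accessibility trends would call enrichment
  unevenly.
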