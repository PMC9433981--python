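# Methods

## Scope and model

`seedcoex` prioritizes candidate targets of a bait transcription factor from
bulk expression data.  The statistical model throughout is Gaussian noise on
the log2 scale (log-normal linear intensities), the standard approximation
for single-channel fluorescence microarrays; every test and correlation is
computed on log2 values, while fold changes and the normalization operate on
the linear scale the thresholds refer to.

## Normalization

Negative (background-subtracted) signals are removed first: a gene
non-positive or missing in every sample is dropped; isolated non-positive
values become missing, never zero, so "filtered" stays distinguishable from
"not expressed".  Each sample is then rescaled so its 75th percentile
(linear-interpolation quantile over observed values) equals a common target
(default 100).  The invariant — recomputed percentile equals the target to
machine precision — is asserted by the tests.  A sample whose values are all
missing, or whose quantile is non-positive, is an error rather than a silent
skip.

## Differential expression

Per gene, a two-sample *t*-test on log2 values between groups resolved from
sample metadata (e.g. seeded vs seedless at one stage, or two named
varieties).  Welch's unequal-variance form is the default because pooled
variances are an extra assumption the data do not need; pooled is a config
switch.  A gene is "up" when p ≤ 0.05 and log2FC ≥ log2(2), "down"
symmetrically, "ns" otherwise; fold change is reported as ±2^|log2FC| with
the sign of log2FC.  No multiple-testing correction is applied by default —
the DEG counts this pipeline is built around are raw-*p* counts — but
Benjamini–Hochberg FDR is available behind a flag.  Degenerate genes
(zero variance in both groups) get p = 1 when means are equal and p = 0
otherwise, avoiding 0/0 without inventing significance.  Genes with fewer
than two observations in either group are reported as untestable, never
dropped silently.

## Profile clustering

Per variety, each gene is summarized as the vector of stage means of log2
expression minus the first stage (so v₁ = 0).  Candidate model profiles are
all integer trajectories starting at 0 with successive steps in {−c..c};
there are (2c+1)^(T−1) of them.  m representatives (default 15, T = 4,
c = 1) are picked by greedy max–min selection seeded at the flat profile,
with distance 1 − Pearson and a Euclidean fallback whenever a trajectory has
zero variance (the flat anchor), since correlation is undefined there; ties
break on lexicographic trajectory order so selection is deterministic.
Genes go to the best-correlated non-flat profile; flat gene trajectories
stay unassigned.

Significance is an exact permutation test: for each of the T! stage
orderings (24 at four stages — small enough that sampling would only add
noise) trajectories are re-ordered, re-anchored and re-assigned; the
expected count per profile is the mean over orderings, and the p-value is
the binomial tail P(X ≥ observed | n assigned genes, E/n).  The binomial
rather than Poisson tail is used because counts are bounded by n.  Profiles
pass at p ≤ α/m (Bonferroni).  T above 8 (40,320 orderings) is rejected
rather than silently sampled.

## Co-expression ranking

Associations with the bait are Pearson correlations on log2 values over all
samples of each dataset, or the highest reciprocal rank: HRR(g) =
max(rank of g in the bait's correlation-sorted neighbor list, rank of the
bait in g's), self excluded, ties broken by gene ID so results are
reproducible.  The composite score multiplies three components:

- **a (concordance)** = (datasets passed) / (datasets configured), where
  passing means r ≥ r_min (default 0.6) for Pearson datasets — r ≤ −r_min
  in the negative-mode ranking — or HRR ≤ hrr_max (default 100).  A count
  and a fraction are rank-equivalent when every gene faces the same D; the
  fraction keeps a in [0, 1].  Genes with a = 0 are excluded: the listed
  set is exactly "co-expressed in at least one dataset".
- **b (intensity)** = product over datasets measuring the gene of |r| or
  1/HRR.  1/HRR preserves the order of the rank measure and is bounded in
  (0, 1], making it multiplicable with correlations; absolute correlations
  are used because a signed product across datasets is ill-defined —
  negative co-expression is a separate ranking (sign_mode), not a sign in
  the product.
- **c (expression level)** = rank fraction of the gene's mean normalized
  intensity in the primary tissue (highest gene = 1, average ranks on
  ties).  Rank fraction rather than raw intensity keeps a·b·c dimensionless
  and invariant to global rescaling.

Genes sort by s = a·b·c descending (ties: higher b, then gene ID); the
top-K (default 100) is the candidate list.  An optional filter demotes
genes that are not down-regulated in seedless samples, defined internally
as a positive SD−SL mean log2 difference in at least two of stages S2–S4.
The bait is excluded by ID.

## Motif scanning

CArG boxes (`CC[AT]{6,8}GG`, widths 10–12) are enumerated per width with
overlap-permitting lookahead, so nested and overlapping matches are all
reported — a single greedy regex pass would undercount.  Because W = A/T is
self-complementary and reverse complement swaps the CC/GG flanks, the motif
is its own reverse complement: minus-strand hits land on exactly the
plus-strand coordinates.  The scanner verifies this identity on every input
and collapses the strands to one '+' hit per site by default (a flag emits
both, mirroring a naive two-strand count).  N never matches.  Hits are
emitted with both 0-based half-open (BED) and 1-based inclusive coordinates
to avoid convention confusion.

## Synthetic data

The generator emulates the study design end to end: 2 seeded + 2 seedless
varieties × stages S1–S4 × 3 replicates; a bait with log2 stage means
(6, 6, 12, 9) in seeded and (5, 5, 6, 5) in seedless samples (sharp S3 peak
vs flat/low); 50 target genes drawn as t = μ + s·(ρ·z_bait + √(1−ρ²)·ε)
with ρ = 0.9 against the observed bait vector, both over the seeded primary
samples and within each auxiliary dataset, so cross-dataset concordance is
real rather than incidental; targets additionally shifted down by
ΔlogFC/2 = 1 in seedless samples at S2–S4; 200 extra genes up by
Δlog2FC = 2 in seeded S3 only; everything else i.i.d. noise (σ = 0.5
log2 units) around per-gene baselines uniform in [6, 10].  Auxiliary
datasets (default two, 30 samples) share gene IDs and embed the same
bait–target structure with the bait varying as in a tissue atlas
(σ = 2 log2 units).  These effect sizes are the package's stated study
conditions for all calibration results; they are synthetic choices of
plausible microarray magnitudes, not measured values.

Promoters are uniform A/C/G/T, rejection-sampled CArG-free (matches are
re-randomized in place until none remain); target promoters then receive
exactly one planted box each at recorded coordinates, accepted only when a
rescan finds precisely the planted sites, so junction artifacts cannot leak
into the truth.  Exact ground truth was preferred over realistic promoter
composition (no dinucleotide model, no GC skew).

A null generator produces the same shapes with no planted structure, for
type-I-error calibration.  Expression and promoter streams derive from
separate child seeds of the one experiment seed, so outputs are bitwise
reproducible and skipping promoters does not perturb the matrices.

What passing tests show — and do not.  The generator has no batch or dye
effects, no probe-level artifacts, no correlated noise between non-target
genes, and Gaussian tails; calibration results (e.g. the 5% null DEG rate)
therefore certify the implementation under its stated model, not robustness
of the t-test or the score to real microarray pathologies.

## Numerical choices

- Quantiles: linear interpolation (`numpy.quantile` default), matching the
  worked normalization examples.
- Ties: gene-ID lexicographic everywhere a sort could be ambiguous (HRR
  neighbor lists, ranking order); lowest profile ID for assignment ties;
  average ranks for expression-level ties.
- Table writers use `%.17g` and the reader a correctly-rounded float parse,
  so write→read is bitwise and stage-wise runs equal end-to-end runs.
- The pipeline fans the one run seed into independent child streams
  (primary / auxiliary / promoters) via `numpy.random.SeedSequence`.

## Problem sizes in the shipped checks

The acceptance computations run at the default study conditions: target
recovery at 5000 genes × 10 simulations; DEG null calibration at 10,000
genes × 5; profile-significance calibration at 1000 trajectories × 20 null
and 20 planted runs; HRR oracle on 100 random 50-gene matrices; motif
oracle on 1000 random 2-kb sequences; determinism on a 1500-gene run.  The
worked regulatory-region example scans a 2147-bp synthetic sequence with
four planted CArG boxes.

## Known limitations

- Pearson-based membership assumes roughly linear log-scale relationships;
  no mutual-rank or spline alternatives are provided.
- The permutation test treats genes as exchangeable units; co-regulation
  between genes (present in real data, absent under the null generator)
  makes the binomial tail anti-conservative in principle.
- The seedless down-regulation filter is a sign test on stage means, not a
  formal interaction test.
- Profile clustering requires complete stage coverage per gene and variety;
  there is no interpolation of missing stages.
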