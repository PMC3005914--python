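# Methods

`nucvarseq` asks whether genomic sequence alone carries information that
distinguishes the target sites of nucleosomes bearing different histone
variants — H2A.Z-only, H3.3-only, or both variants at once ("double
variant") — and provides the full chain of computations to answer it:
sequence preparation, canonical k-mer featurization, RBF-SVM
discrimination, Fisher-score motif ranking and motif autocorrelation.
Because the original ChIP-Seq-derived nucleosome calls are external data,
the package ships a synthetic-data generator that plants known signal, so
every stage is validated end to end against ground truth.

## Sequence preparation

Nucleosome calls arrive as BED intervals with the variant label in the
name column. Each call is truncated/extended to a fixed length (default
150 bp, roughly the nucleosomal DNA length) about its midpoint. When the
interval's parity differs from the target's, the extra base is assigned to
the right (3' in genome coordinates): `new_start = (start + end - target
+ 1) // 2`. This rule is deterministic, strand-agnostic and idempotent.
Standardized intervals that would leave the chromosome are excluded and
counted.

Genes are deduplicated by expression-array probe id (first record in input
order wins; records without a probe id, or on `*random*`/`*_hap*` contigs,
are dropped). Each surviving gene contributes a TSS-vicinity window of
10 kb upstream and 2 kb downstream, reflected for minus-strand genes. A
nucleosome "belongs" to the TSS vicinity when its midpoint lies inside at
least one window — midpoint membership gives every call a single
unambiguous in/out decision where an overlap rule would need an arbitrary
threshold.

Extracted sequences are uppercased; any sequence containing an ambiguous
base is excluded and counted. When the source FASTA is soft-masked,
sequences with more than 50% lowercase bases are excluded as
repeat-dominated (threshold configurable); this reproduces the intent of
repeat exclusion without rerunning a masker. Balanced training sets are
drawn without replacement per class with a fixed seed.

All coordinates are 0-based half-open; the TSS column is a 0-based
position.

## Canonical k-mer features

A k-mer and its reverse complement describe the same double-stranded
word, so both strands' occurrences are collapsed onto a canonical
representative (the lexicographically smaller of the pair). For k = 1..6
there are 2, 10, 32, 136, 512 and 2080 canonical k-mers —
(4^k + 4^(k/2))/2 for even k (reverse-complement palindromes exist only at
even k), 4^k/2 for odd — 2772 features in total.

Counting slides a width-k window with step 1; a window containing an
ambiguous base is skipped and reported. Each k-block is normalized by the
number of valid windows of that k, so every block of an N-free sequence
sums to one. Per-k relative frequency makes the features length-invariant
and the blocks mutually comparable; a raw-count mode is not exposed
because every downstream consumer in the package expects frequencies.
Featurization is exactly strand-symmetric: a sequence and its reverse
complement produce identical vectors.

## RBF-SVM classification

The two classes (labels ±1) are separated by a soft-margin SVM with the
radial basis function kernel K(x1, x2) = exp(−γ·‖x1 − x2‖²). Defaults:
γ = 1/n_features (scale-free standard default; with per-k-normalized
features the pairwise distances are well inside the kernel's dynamic
range) and C = 1, with no per-dataset tuning. The dual quadratic program
is solved by libsvm via scikit-learn; the fitted model re-exposes the dual
coefficients, support vectors and bias, and the test suite asserts the KKT
box constraint 0 ≤ αᵢ ≤ C and the equality Σ αᵢyᵢ = 0.

Performance is measured by the ROC score (AUC) of held-out decision
values under stratified 10-fold cross-validation: the per-fold AUCs are
averaged (not pooled), and a one-sample, one-sided t-test compares the
fold AUCs against the 0.5 random baseline. AUC is computed by the
Mann–Whitney identity with ties counted one half. Stratification
guarantees both classes appear in every fold; fold assignment is
deterministic under the run seed.

Two caveats are deliberate. First, the t-test over CV folds is mildly
anti-conservative because folds share training data; on null data its
empirical type-I rate at α = 0.05 sits above the nominal 5% (clearly so
for small datasets, mildly for 300-per-class sets). The package keeps the
procedure because it is the field's convention for this analysis; the
calibration tests therefore bound the rejection rate at 10%, not 5%.
Second, the kernel bandwidth is a free parameter; results reported by the
package always echo γ and C.

## Fisher-score motif ranking

For feature j with class means x̄ⱼ¹, x̄ⱼ², overall mean x̄ⱼ and unbiased
within-class scatters s_k = 1/(n_k−1) Σ (x − x̄ⱼᵏ)²,

    F(j) = ((x̄ⱼ¹ − x̄ⱼ)² + (x̄ⱼ² − x̄ⱼ)²) / (s₁ + s₂).

The numerator captures between-class separation, the denominator
within-class scatter. F is invariant under affine rescaling of a feature
and under swapping the class labels. Features with zero pooled scatter
score 0 when the class means agree and +∞ (ranked first) when they
differ. Every motif is annotated with the class its mean is higher in
("+" for the +1 class), and the full ranking plus a top-20 view
(Order / Motif / F-score / Direction) are emitted. Scores are computed on
the same normalized features the classifier consumes.

## Motif autocorrelation

For motif X of length l in a sequence of length L, k denotes the
start-to-start distance between two occurrences. The pair probability is
P_XX(k) = N_XX(k)/(L − k − l + 1) — the denominator counts the (i, i+k)
position pairs that fit — and the single-occurrence probability is
P_X = N_X/(L − l + 1). The covariance C_XX(k) = P_XX(k) − P_X² is zero in
expectation for independent placement; positive peaks mark enriched
spacings. Start-to-start distance is the only reading consistent with the
pair-count denominator above: a tandem CA run then peaks at k = 2, 4,
6, … A motif may be paired with its reverse complement (the CA/TG
convention): occurrences of either member form one union set, used
consistently for both P_XX and P_X. The periodogram of a set is the per-k
mean of per-sequence covariances; sequences too short for a given k are
excluded from that k's mean and counted.

Periods are declared by a permutation null rather than visual inspection:
each of (default) 200 replicates shuffles every sequence with the
Altschul–Erikson dinucleotide-preserving shuffle — preserving the
occurrence count of any dinucleotide motif while destroying spacing — and
k is called a period when the observed mean covariance exceeds the null's
99th percentile at that k. The default distance range is 1..50 for 150 bp
sequences; distances whose pair denominator vanishes are omitted.

## Synthetic data

The generator emulates two-class nucleosomal sequence sets: fixed-length
sequences (default 150 bp) drawn iid from a configurable background
(uniform by default; a 40% GC preset approximates human promoter-distal
composition), with class-differential motif insertion and an optional
planted periodic run. Per-sequence insertion counts are Poisson with the
configured per-sequence rate (the standard null for motif occurrence);
each insertion overwrites the background at a uniform position, and
overlaps are allowed — planted counts are verified empirically by the
tests, not by construction. The planted period writes `copies` copies of
a motif at a fixed start-to-start spacing into a configured fraction of
class-1 sequences at a uniform run start.

The planted-signal study condition used by the analysis scripts and the
end-to-end tests plants CA at 6 copies/sequence plus CAG at 2 (class 1,
the "double" stand-in) against AAT at 2 plus TA at 3 (class 2), with a
spacing-2 CA run of 8 copies in half of class 1 — moderate effect sizes
chosen once to mirror the qualitative contrast the pipeline is meant to
detect (CA/TG-family enrichment with even-k periodicity versus AT-rich
enrichment); they are generator settings, not claims about real data.
What the generator does not emulate: ChIP-Seq read noise and peak-calling
artifacts, repeat structure, CpG-related mutational processes, genomic
autocorrelation of composition. Passing tests therefore demonstrate that
the pipeline recovers planted signal of the configured kind and size, not
that real nucleosomal sequences carry such signal.

The genome fixture is a random genome (uniform composition) with
nucleosome intervals of 80–220 bp labeled `double`/`h2az_only`/`h33_only`
in the BED name column, plus a gene table with random strands and TSS
positions; it exists to exercise the preparation stage's geometry and
I/O round-trips.

## Problem sizes and numerical choices

The study conditions for the statistical checks: null calibration uses
300 sequences per class with labels independent of content (the
random-baseline average is taken over 20 seeded replicates); the
trivially-separable check plants 20 copies of a hexamer in every class-1
sequence, which drives the corresponding canonical-hexamer frequency to
~0.8 of the k=6 block and makes the classes linearly separable in feature
space. The 50-replicate rejection-rate check runs at the same 300+300
size. End-to-end pipeline tests use 120-sequence pools with 80+80
training subsamples and 60-replicate permutation nulls: large enough for
the planted effects to dominate sampling noise at the configured effect
sizes, small enough to keep the default test run fast.

Ties in the F-score ranking are broken by feature-index order (k
ascending, then lexicographic), so tables are byte-reproducible. AUC ties
are handled by midranks. All random draws flow through
`numpy.random.default_rng` seeded from the run configuration; identical
configuration and seed give byte-identical outputs, including the written
reports.

## Known limitations

* Real-data mode expects already-called nucleosome intervals; no peak
  calling is included.
* The repeat filter is a soft-masking heuristic, not RepeatMasker/TRF.
* The CV t-test's anti-conservatism (above) is inherited from the
  conventional procedure; treat borderline p-values accordingly.
* No kernel/hyperparameter search is provided, by design.
* Period calling tests each k marginally against its own null quantile;
  with ~10 distances inspected, an isolated borderline call at the 99th
  percentile is within expectation for null data.
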