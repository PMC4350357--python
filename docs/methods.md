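# Methods

## Statistical model and pipeline

The pipeline operates on probe-set × sample intensity matrices with an
explicit scale flag (linear or log2). The canonical order of operations is

1. quantile normalization (linear scale),
2. log2 transform with a floor (default 1.0),
3. baseline filter: keep probes whose **maximum** intensity across samples
   reaches a threshold (50 for mRNA, 800 for miRNA arrays),
4. variation filter: keep probes with |mean paired tumor−normal log2
   difference| ≥ log2(2),
5. per-probe paired t-test, two-sided p from the t distribution on n−1 df,
6. Benjamini–Hochberg step-up at α = 0.05.

The paired test is the right design because matched tumor/normal tissues from
one patient share a patient-level intensity offset; differencing removes it.
The two filters precede testing, so the BH family is the set of probes that
are both expressed and changed — this matters for type-I behavior (below).

### Zero-variance paired differences

`paired_t_test` flags probes whose paired differences have zero variance and
reports a missing p rather than p = 0: an isolated t-statistic of a constant
difference is undefined and tiny constant offsets (e.g. quantization) must
not become top hits. Inside `derive_signature` the situation differs: a probe
reaching the test has already shown a ≥ 2-fold mean change, so a *constant*
≥ 2-fold difference in every pair is maximal, not degenerate, evidence — such
probes enter BH with p = 0 and keep their `zero_variance` flag. This is also
the noise-free limit in which the planted-truth recovery guarantees hold.

### Small strata

With fewer than 3 resolvable pairs (in practice: the single MYB-low tumor),
`derive_signature` degrades to a descriptive rule — significant = passed both
filters — with the test columns left missing and the mode recorded in the
table attributes and output header. A t-test on one pair is meaningless; the
fold-change comparison is what the corresponding high-vs-low figures in this
field actually plot.

### Group comparison

The fusion-positive vs fusion-negative contrast is a per-probe fixed-effect
pooled-variance F test (F = t² on 1 and n₁+n₂−2 df) with BH across probes. A
patient random effect is not identifiable with one tumor per patient, so no
mixed model is fitted.

### Quantile normalization

Every sample's sorted vector is mapped onto the across-sample mean of order
statistics; ties within a sample receive the mean of the reference values
they span. On tie-free data (continuous intensities) the transform is exactly
idempotent; with ties, idempotence holds only for the tied entries, which is
why the idempotence guarantee is stated for continuous data.

## Exon-level rearrangement calling

Per tumor, the delta vector `d_e = log2(tumor_e + 1) − log2(normal_e + 1)`
(pseudocount 1 keeps zero intensities finite) is scanned over splits k — last
retained 5' exon, 1-based — with a two-segment t-like statistic. Numerical
choices:

- **Search range** k ∈ [min_seg, E−1] with min_seg = 2: the 5' segment needs
  ≥ 2 exons for a meaningful mean, while the 3' segment may be a single exon
  because the most common MYB breakpoint lies in the terminal-exon region and
  a drop after exon E−1 must remain callable.
- **sd floor** 0.05 log2 on the pooled within-segment sd, preventing infinite
  statistics on noise-free profiles; ties in S(k) resolve to the smallest k.
- **Thresholds** τ = 4, min 5' elevation 1.0 log2, max 3' elevation 0.5 log2.
  The three-way outcome (positive / negative / indeterminate) keeps uniform
  over-expression negative and refuses to call an elevated-3' changepoint
  either way. At these defaults, simulated operating characteristics are
  status accuracy ≥ 0.98 and exact-breakpoint recovery ≥ 0.95 at noise
  sd 0.3 (5'−3' step of 2 log2), with false-positive rate ≤ 0.01 on uniform
  profiles.
- **Terminal alleles**: for positive calls, a 3' segment mean ≤ 0.5 log2
  above zero (inclusive) is reported as `silent` — no detectable wt or
  reciprocal transcript — else `residual`.
- Exon rows with missing values (an exon absent from the array) are dropped
  with re-indexing at read time, never imputed; the breakpoint coordinate
  then refers to the post-drop ordering, as stated in every output header.

## Enrichment and integration

Fisher's exact test on the 2×2 table (in/out signature × in/out set) is
computed from the hypergeometric pmf; the two-sided p sums probabilities ≤
the observed one (with a 1e-7 relative epsilon, the convention of standard
implementations), and the one-sided enrichment tail is reported alongside.
The default universe is the baseline-filtered probe set — the background that
was actually eligible for testing — not the genome. Dependence classification
is restricted to genes activated in the MYB-high stratum; with a single
MYB-low tumor, the low stratum alone is too noisy to nominate genes.
Mutation integration keeps up-regulated significant genes with ≥ 1 mutation
of an allowed class (default missense/truncating), sorted by fold change.
miRNA–mRNA links require both members significant, opposite directions, and
presence in the supplied prediction map.

All output tables carry total orders (q, then |log2 FC|, then probe ID; ties
in clustering broken by sample ID) and are written with a fixed float format,
so repeated runs are byte-identical.

## The synthetic cohort generator

`generate_cohort` emulates the data structure the analysis assumes, on the
log2 scale: gene baselines ~ N(7, 1.5); a patient random effect ~ N(0, 0.2)
added to both members of a pair (this creates the within-pair correlation
that motivates the paired test and makes the paired-vs-unpaired power
difference observable); i.i.d. Gaussian noise (sd 0.4 by default) added
independently to tumor and normal; planted multiplicative fold changes
applied to tumors before noise. Because the patient effect cancels in the
tumor/normal ratio, at noise sd 0 every planted gene's realized fold change
equals its configured value exactly.

Defaults and their rationale:

- 12 tumor/normal pairs; 5000 probes; 100 up- and 60 down-regulated planted
  genes with folds uniform in [2, 30]; MYB fixed at 18-fold, KIT at 5,
  FGFR1 at 4; VCAN (16) and HAPLN1 (14) lead a 16-gene ECM block drawn in
  [8, 13] so the ECM set is top-fold yet below MYB. Named fixed folds are
  clipped to the configured ceiling so narrowing `fc_range` bounds every
  non-MYB gene.
- Planted signature genes have their baselines floored at log2 intensity 6.5
  (~90): they emulate transcripts the study detected, so they must clear the
  baseline filter; null genes keep the untruncated baseline distribution.
- One MYB-low tumor (by default the first fusion-negative tumor; always
  fusion-negative) carries MYB at fold 1 and loses the planted
  MYB-dependent and MYB-associated effects while keeping every independent
  effect. Dependence labels (30 dependent / 10 associated by default) are in
  the truth tables, and the emitted ChIP target list contains the dependent
  genes plus about half of the independent ones plus null background, giving
  a signature overlap near 50%.
- The exon profile has 15 exons; fusion-positive tumors carry the full MYB
  induction on exons 1..k and only the configured residual (default 0) after
  the planted breakpoint (uniform in 8–14); fusion-negative MYB-high tumors
  are uniformly elevated; the MYB-low tumor is flat.
- The miRNA matrix has 847 probes with 16 down- and 6 up-regulated planted
  species; miR-150 (down 4-fold, targeting MYB) and miR-29 (down 2.5-fold,
  targeting HAPLN1) are the named inverse pairs; planted miRNA baselines
  ~ N(12, 0.5) clear the 800-intensity filter while background miRNAs
  ~ N(10.5, 1.2) partly do not.
- The mutation table plants RUNX1 (missense ×2) and NOTCH1 (truncating)
  among the up-regulated genes against TP53/FBXW7 (outside the signature)
  and one down-regulated mutated decoy, so the expression×mutation
  intersection has a known answer.

`generate_null_cohort` disables every planted effect; tumors and normals are
exchangeable per gene. Under the full derivation the variation filter makes
zero discoveries the overwhelmingly likely outcome (the mean paired delta of
a null gene has sd ≈ 0.16 log2 against a threshold of 1), so the null
zero-discovery rate is ~1; under t-test+BH alone the probability of at least
one rejection at the global null is α by construction, which is why type-I
checks run the full composition.

### What the generator does not emulate

Probe-level (pre-summarization) data, batch effects, array-to-array
distribution differences (columns are exchangeable by construction, so
quantile normalization is nearly a no-op on synthetic data), subtype-specific
MEC/ADC structure (labels exist but only ACC-vs-normal effects are planted),
correlated gene modules, and intensity-dependent variance. Passing tests
therefore demonstrate the correctness and calibration of the algorithms under
the stated generative model, not performance on real arrays.

### Known edge cases

The marker-low stratification rule (tumor ≤ mean(normals) + 2·sd(normals))
compares a tumor against the between-patient spread of normals; a MYB-low
tumor whose patient offset sits in the upper tail of that spread can be
missed even without noise (a few percent of seeds). This is a property of
the rule, kept as specified; a paired variant would cancel the offset but
would no longer express "indistinguishable from basal levels in normal
tissue".

## Problem sizes

The test suite and the acceptance script use the default cohort sizes
(12 pairs × 5000 genes), 50 null replicates for type-I control, 20 replicates
for recovery, 200 + 1000 exon profiles for the fusion caller, 500 randomized
profiles for the changepoint oracle, all universes ≤ 25 (23 750 tables) for
the Fisher oracle and 1000 random vectors for the BH oracle; the full
acceptance run completes in well under a minute on one CPU.
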