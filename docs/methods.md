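# Methods

## The analysis model

The package targets the standard design of behavioral-characterization
transcriptomics in aging rodents: two age groups (defaults 11 young,
20 aged), each animal scored on an attentional set-shift task
(trials-to-criterion, TTC; the criterion is eight consecutive correct
trials, so TTC ≥ 8 and higher is worse) and a water-maze probe trial
(discrimination index DI = (G − O)/(G + O) ∈ [−1, 1]), with bulk
RNA-seq gene counts per region (mPFC, CA1, white matter).

The screening philosophy is deliberate: per-gene tests run at an
uncorrected α (0.025), accepting that confidence in any single gene is
low, and inference is carried by aggregate structure — gene-set
enrichment, cross-study directional agreement, and composite indices.
Consequently no multiple-testing correction is applied to the screens
themselves; correction (Benjamini–Hochberg) appears only across GO
terms in the over-representation test.

### Age screen

One-way ANOVA per gene between young and aged on log2(normalized + 1)
values. With two groups the F statistic is identically the squared
pooled-variance t, which the tests verify to 1e-10 relative error. A
Welch variant is available (`welch=True`) as a sensitivity analysis.
Direction and fold change are computed on the linear normalized scale;
the signed-fold convention reports ratios below 1 as the negative
reciprocal (0.84 → −1.19), the form used in published fold tables.

Whether such screens should run on raw, normalized, or log counts is
genuinely underdetermined; log2(normalized + 1) is the default here
(variance-stabilized, suitable for t/F tests) and the linear scale
remains available through `NormalizedMatrix.linear()` and
`normalize(log2=False)`.

### Correlation screen and critical r

Gene-wise Pearson correlation with a behavioral score, restricted to
aged animals so age itself cannot drive the correlation. Significance
uses the exact t transform with df = n − 2, two-tailed. The two-tailed
choice is forced by the reproduction of the published cutoff pair: at
α = 0.025 and n = 20, inverting the t CDF gives critical r = 0.4993,
matching the printed 0.499 only under the two-tailed reading.
`critical_r` is checked against a brute-force grid inversion oracle.

Sign semantics differ by measure and the report keeps both explicit:
for TTC (higher = worse), r > 0 means expression rises with
impairment; for DI (higher = better), r > 0 means expression rises
with better learning.

### Cross-study concordance and the expected-direction FDR

A prior study's gene list carries an expected direction (±1) per
symbol. Matching into the current data is case-insensitive symbol
equality (handles human/rat capitalization conventions; ortholog
inference is out of scope — the matched list is taken as given). With
T matched genes:

1. **Agreement**: observed direction is the sign of the linear
   group-mean difference; a gene with exactly equal means cannot match
   a ±1 prediction and counts as disagreeing.
2. **Chi-square**: 1-df goodness-of-fit of (n_same, T − n_same)
   against (T/2, T/2), no continuity correction. Note: for 203 of 318
   concordant genes this statistic is 24.35; a published value of
   11.86 for that split is not reproducible under any documented
   variant (Yates correction or alternative null proportions were
   checked), so the package reports the defined statistic.
3. **Directed tests**: per-gene one-tailed pooled t in the predicted
   direction at α (default 0.05). Genes with zero variance in both
   groups stay in T — T is defined as the number of genes *tested*
   (matched), not post-hoc filtered — but can never be significant.
4. **FDR** = (T·α)/n_sig: the chance-expected number of directed hits
   divided by the observed number. It is 1 exactly when n_sig = T·α,
   strictly decreasing in n_sig, and undefined (NaN) when n_sig = 0.
   Reported FDRs are conventionally rounded to two decimals; full
   precision is retained internally.

### Composite index, classification, maze and qPCR arithmetic

The index score z-scores each gene of a set across the animals that
carry the behavioral score, averages within animal, and correlates the
average against the standardized score. With a single gene this equals
that gene's correlation exactly; with a positively inter-correlated
module, averaging suppresses independent noise and raises the
composite correlation above typical single-gene values. Whether the
z-standardization should use aged animals only or all animals is
ambiguous in the source designs; the subset is simply the set of
animals whose scores are passed in, making the choice explicit at the
call site (aged-only when reproducing the behavioral analyses).

Mean-split classification labels an aged animal AI iff its TTC is
strictly above the aged-group mean ("delayed" shifting reads as
strictly greater; ties are AU). Labels are invariant to affine
rescaling of TTC.

ΔΔCT: technical replicate CTs are averaged (replicate handling is
rarely stated in assay descriptions; the arithmetic mean is the
default), then ΔCT = CT_target − CT_reference per sample,
ΔΔCT = ΔCT − mean control ΔCT, fold = 2^(−ΔΔCT). Group comparisons
default to the ΔΔCT (log) scale where normality is more plausible;
the fold scale is available. The reference gene cancels per-sample
plate offsets exactly, and the control group's geometric-mean fold is
1 by construction.

## Normalization details

Median-of-ratios size factors use only genes with nonzero counts in
every sample (their geometric mean is well defined). For an even
number of reference genes the lower median is taken; the unit test
against an established implementation of the same estimator uses an
odd gene count so the conventions coincide. Scaling one sample's
counts by c leaves every normalized profile unchanged up to a single
shared factor c^(1/n) from the geometric-mean reference — the property
tests assert this exact equivariance. Zero-variance rows are excluded
(with a warning) from z-scoring rather than emitting NaN.

Spike-in QC fits log10(observed + 1) on log10(expected) by least
squares and passes iff R² > 0.9 (strict) and at least 60 transcripts
are detected, both gates as literally specified.

## The simulator

`generate_counts` draws counts from a negative binomial with
var = μ + φμ² (default dispersion φ = 0.1, typical of bulk brain
RNA-seq), baseline log2 means Normal(5, 1.5) (median ≈ 32 counts),
and per-sample library factors log-normal with spread 0.2 normalized
to geometric mean 1. Defaults mirror the target study conditions:
11 + 20 animals, 15,000 genes, ~700 age-responsive genes at |log2
fold| = 1 (half up; aging cohorts show immune-type genes up and
synaptic genes down, which the planted split emulates statistically,
not ontologically), and ~400 behavior-correlated genes, 73% with
positive sign.

Behavior-correlated genes receive β·z(TTC) on the log2 mean of aged
animals, with β solved per gene from the delta-method noise
approximation var(log2 X) ≈ (1/μ + φ)/ln²2 so the realized Pearson
correlation sits near the target (empirically, a target of 0.7 yields
a median realized |r| ≈ 0.69). TTC scores are real-valued by default
(keeps correlation targets exact) with an `integerize_ttc` flag that
rounds and floors at 8, the task criterion. Aged TTC is a two-Gaussian
AI/AU mixture; the defaults (AU mean 30, AI mean 78, SD 10, 45%
impaired, young mean 25) put the expected aged mean near 51.6,
anchored to the published aged mean-split of 51.7 — the only printed
anchor for these otherwise free parameters.

Spike-in fixtures place expected concentrations on a uniform log10
grid over six decades and generate observed counts as
10^(a + b·log10(expected) + ε) − 1, so the QC fit is exactly linear at
ε = 0 (the −1 offset mirrors the +1 in the QC regression). qPCR CT
fixtures use CT = baseline − log2(expression) + noise, reference gene
held at fold 1.

All randomness flows from a single integer seed through independent
child streams per generator, so `generate_behavior(config)` returns
the same table whether called directly or from within
`generate_counts`; equal seeds give byte-identical outputs.

### What the simulator does and does not emulate

It reproduces the statistical skeleton — overdispersed counts, library
size variation, planted mean shifts and planted expression–behavior
correlations, a bimodal impairment distribution. It does not model
gene–gene co-expression beyond what shared behavioral signal induces,
GC/length biases, batch structure, or ontologically coherent gene
sets. Passing recovery tests therefore demonstrates that the
*statistics* behave as designed under the assumed generative model,
not that the pipeline is robust to every artifact of real libraries.

## Calibration and problem sizes

On null data (no planted effects, 20 cohorts of 5,000 genes) both
screens reject at 2.4–2.5% for nominal α = 0.025 — the small
conservative deficit (~0.0005–0.001) reflects t-tests on
log-transformed, mildly skewed count data at n = 11/20 and is within
three binomial standard errors of nominal in the acceptance check.
Planted age genes at |log2 fold| = 1 are recovered with ~98%
sensitivity and planted behavior genes at r = 0.7 with ~94%, both
comfortably above the 0.8 acceptance floor (analytic power at r = 0.7,
n = 20, two-tailed α = 0.025 is ≈ 0.9).

Test and acceptance runs use 200–5,000-gene cohorts and 5–100 seeds
per property — sizes chosen so each Monte-Carlo estimate has small
enough error for its assertion while the whole suite stays fast.

## Known limitations

- The pooled t/ANOVA assumes equal group variances; the Welch option
  exists but is not the default, matching the one-way-ANOVA framing.
- The expected-direction FDR is an expectation ratio, not a
  BH-adjusted q-value; it can exceed 1 and is reported as-is.
- GO over-representation is a plain hypergeometric/BH test at the term
  level; fuzzy functional-annotation clustering of terms is explicitly
  out of scope, so cluster-level significance values from tools that
  do cluster are not comparable.
- Case-insensitive symbol matching is a pragmatic cross-species rule;
  genuine ortholog mapping must happen upstream.
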