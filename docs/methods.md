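# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-cohort generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Data model

All analyses operate on dense feature × sample matrices. Expression values
are log2-scale array intensities after upstream normalization; methylation
values are beta fractions in [0, 1]. Matrices must be complete: detection
filtering and normalization are upstream concerns, so a missing or
non-finite cell is rejected at read time rather than imputed. Samples are
*cumulus-cell clusters*; the sample sheet maps each cluster to its donor,
treatment cycle, stimulation protocol (short = GnRH antagonist,
long = GnRH agonist) and pregnancy outcome. An *analysis unit* is one
donor-cycle together with its ≥ 2 non-pooled clusters; the clusters act as
within-unit replicates, which is what makes unit-vs-unit testing possible
at all — with a single cluster per unit the pair-level variance would be
undefined.

Probe-level expression matrices are collapsed to gene level by keeping, per
gene, the probe with the largest variance across samples (ties broken by
probe id). The collapse rule is a convention, not an inference: it is
deterministic, idempotent, and standard for array data. Both probe- and
gene-level matrices can be fed to any stage.

TSS offsets are signed, strand-aware base-pair distances with 0 at the TSS
and negative values upstream. Window membership uses the closed interval
[−w, +w]; the default window is 10 kb on either side.

## Differential testing

Two-group comparisons use the pooled-variance Student *t* (two-sided); this
matches the defaults of the classic array-analysis suites this pipeline
mirrors. Welch's test is available behind a flag. The effect column is the
plain mean difference `comparator − reference` on the matrix scale (a log2
fold change for expression, a delta-beta for methylation), and the
reference group is always named explicitly in results. Multi-group
comparisons use one-way fixed-effects ANOVA with (k−1, n−k) degrees of
freedom.

Degenerate features — zero within-group variance — are never silently
dropped: equal means give the null result (statistic 0, p = 1); unequal
means are flagged and assigned the smallest representable positive p, so
they sort first but remain identifiable.

Multiple testing uses Benjamini–Hochberg step-up q-values ("FDR < 5%" is
the pipeline's significance convention); the family-wise procedure used for
the small regulator-level test families is Holm step-down, chosen because
it is assumption-free. Both delegate to `statsmodels.stats.multitest`.

## Regulator activation scoring

For a differential selection with up/down directions and a catalog of
signed regulator→target edges (+1 activating, −1 inhibiting):

- **Overlap p-value**: right-tail hypergeometric probability of drawing at
  least the observed number of the regulator's targets into the selection,
  given the measured gene universe. Targets outside the universe are
  dropped before evaluation.
- **Activation Z-score**: `z = (Σ sᵢ)/√N` over the N targets inside the
  selection, with `sᵢ = +1` for direction/edge-sign concordance under an
  activated regulator and −1 otherwise. All edges carry unit weight — no
  edge-confidence weighting is applied, making this the unweighted special
  case of published causal-analytics scoring. With no overlapping target
  the Z is undefined and reported as null.

Defaults: the selection feeding the scorer is p < 0.05 with directions;
regulators with fewer than 4 selected targets are omitted (`min_overlap=4`)
because Z on tiny overlaps is dominated by single genes. Both are
configurable. The same machinery scores any signed or unsigned gene-set
catalog (pathways, disease/bio-function categories); unsigned sets are
meaningful for the overlap p only.

Exact numeric agreement with proprietary curated-catalog implementations is
out of scope — the catalog contents differ — but sign and ranking recovery
are verified against planted ground truth.

## Pairwise stratification

For every (reference, comparator) unit pair the pipeline runs the
cluster-level two-group test (effect = comparator − reference), selects at
p < 0.05, and scores the regulator catalog. A comparator's score for a
chosen regulator is its mean Z across reference pairs; the classification
rule is sign-based with a configurable dead zone: mean z > +z_cut → "high",
< −z_cut → "low", otherwise "middle". References are "middle" by
construction (they sit at zero distance from themselves), ties go to
middle, and the default z_cut is 0 with |z| ≥ 2 flagged as conventionally
confident. Group differences in Z between the high and low pair sets are
assessed per regulator with the pooled *t* and Holm correction; the derived
three groups are then tested for molecular separability with the per-feature
ANOVA at FDR < 5%.

## Expression–methylation correlation

Spearman ρ (average ranks for ties) per (gene, CpG) pair over the shared
samples, restricted to pairs with |TSS offset| ≤ window; p-values use the
t approximation, which is also what the standard library routines use for
these sample sizes, with an exact permutation p available for n ≤ 8.
Records are binned into twenty 1-kb bins spanning [−10 kb, +10 kb]; per bin
the counts of significant (default p < 0.01) negative and positive
correlations and their mean −log10 p are reported. The cohort-level readout
is the negative:positive ratio in the two central bins. Clinical screens
use Pearson correlation because the clinical scalars are interval-scaled
measurements; each cluster inherits its cycle's clinical value, since
clinical data exist only at cycle level.

## Clinical response curves

Each cycle's estrogen (pg/mL), endometrium thickness (mm) and lead-follicle
size (mm) series is fitted with a straight line by OLS. A linear form was
chosen because the series are short (3–6 points) and the analysis consumes
a single rate per cycle; a log-linear variant for estrogen can be obtained
by transforming the input. The day-12 summary prefers the observed day-12
measurement and falls back to the fitted prediction. The parameter table
(three day-12 values, three slopes, plus spindle presence, zona
birefringence, pronuclear pattern and age) is screened with all-pairs
Pearson correlations at a default α = 0.05; zero-variance columns are
excluded first.

## Resampling heterogeneity

`jackknife_stability` repeats the two-group test `n_tests` times (default
10), each time dropping `ceil(0.10·n)` samples uniformly at random without
replacement (labels preserved, group proportions not forced). Each run's
selection is compared with every other run's by intersection percentage,
defined as Jaccard similarity × 100; two empty selections count as
identical (100). The *global variance* is the sample variance (n−1
denominator) of the off-diagonal percentages. The feasibility check is
deterministic and conservative: every group must retain ≥ 2 samples even if
all dropped samples came from it.

Two conventions here are deliberate choices among defensible options and
only the *ordering* of variances between cohorts carries scientific weight:
the denominator (overlap-over-smaller-set is available as an option) and
the selection rule. The benchmark comparisons select at q < 0.05 rather
than raw p < 0.05: with a raw-p rule, the α-level false positives (≈ 100
features at 2000 × 0.05) churn freely between subsamples and dominate the
variance of *any* cohort, masking the heterogeneity contrast the statistic
exists to measure.

## The synthetic generator

`generate_cohort` draws, per gene, a baseline N(8, 1.5²) on the log2 scale,
then adds: a per-donor offset (Gaussian with σ_d, or bimodal ±σ_d for the
heterogeneous regime), a protocol delta (±1.0 on 100 random genes, applied
to long-protocol samples), a response-group delta (β × edge sign ×
direction on each active regulator's targets), and N(0, σ_e²) cluster
noise. Methylation betas follow a logistic model:
`beta = expit(b₀ + c·dev + ε)` with baseline logit b₀ ~ N(0, 1.5²), noise
ε ~ N(0, 0.3²), and coupling `c = −2` for CpGs within the coupling window
of their gene's TSS (0 outside), where `dev` is the gene's expression
deviation from its baseline in that sample. Clinical series are linear in
day with group-specific slopes (estrogen 220/180/140 pg/mL/day,
endometrium 0.75/0.60/0.45 mm/day, lead follicle 1.50/1.25/1.00 mm/day for
high/middle/low) plus observation noise, observed on days 5, 7, 9 and 11 so
day 12 exercises the prediction path.

Cycle-level group labels (high/middle/low) are assigned by deterministic
quota; pregnancy-positive cycles are exactly the middle group, mirroring a
positive cohort flanked by over- and under-stimulated negative groups. The
default cohort is 8 donors × 1 cycle × 3 clusters (24 samples), 2000 genes,
1000 CpGs, a 10-regulator catalog with 40 targets each (70% activating
edges), σ_d = 0.3, σ_e = 0.5, β = 1.5 — sizes and effects at which planted
structure is recoverable by the pipeline's own statistics at the cohort
scale of the motivating study. One global seed fans out through
`SeedSequence.spawn` to independent per-component generators, so the same
seed reproduces every artifact bit-for-bit.

Named presets pin the benchmark designs: `null_config` (20 samples, no
effects), `two_group_config` (one regulator activated in the negative
arm), `heterogeneous_config` (bimodal donors, β = 0.8) and
`homogeneous_control_config` (no donor structure, β = 2.0 — a clean strong
signature playing the role of a male-vs-female blood control).

What the generator does **not** emulate: probe-level intensity noise and
multi-probe genes (expression is simulated at gene level; probe collapse is
tested with explicit fixtures), chip/batch effects, detection p-values,
realistic genome coordinates beyond signed TSS offsets, distance-decay in
the methylation coupling (it is a step function of the window), nonlinear
hormone kinetics, and any correlation between the embryology scores and
molecular state. Passing recovery tests therefore demonstrates that the
statistics recover the structure they model, not that real cumulus cohorts
satisfy those models.

## Numerical conventions

- TSV is the interchange format everywhere; matrices are written with 17
  significant digits and read back with round-trip float parsing, so
  write∘read is the identity on doubles.
- p-values are required to lie in (0, 1]; degenerate tests report the
  smallest positive double rather than 0.
- PCA centers features internally and orders components by decreasing
  explained variance; requesting components beyond min(features,
  samples − 1) is an error.
- Ties: Spearman uses average ranks; probe collapse and result orderings
  break ties by identifier so outputs are stable; classification ties go to
  "middle".
- All randomness flows from explicit integer seeds (numpy `default_rng`);
  CLI stages rerun with the same inputs and seed produce byte-identical
  files.

## Known limitations

- The pooled t and one-way ANOVA assume homoscedastic Gaussian noise
  within groups; no empirical-Bayes variance moderation is applied, so
  power at 2–4 replicates per unit leans on the planted effect sizes.
- Unit-pair Z-scores that share a reference unit are not independent; the
  group *t*-test on Z values treats them as exchangeable observations,
  which is the procedure being reproduced rather than a recommendation.
- The activation Z treats every edge equally; catalogs with very uneven
  edge quality will dilute z toward 0.
- The heterogeneity statistic's absolute value depends on the intersection
  denominator and selection rule; only comparisons under identical settings
  are meaningful.
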