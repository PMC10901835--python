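# Methods

`tempro` analyzes paired mRNA/protein stimulation time courses: which
features respond, when their two molecular layers agree, and how long
translation lags transcription. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Study design assumed

The pipeline expects the design it simulates: two cell subsets (CD4, CD8
T cells), six timepoints (0, 6, 12, 24, 72, 168 h post-stimulation), and
three donor replicates, measured in parallel by RNA-seq (gene counts) and
label-free DDA proteomics (maxLFQ-style intensities). Timepoints are always
stored in hours (3 d = 72, 7 d = 168) to avoid unit mixing. All contrasts
compare a stimulation timepoint against the 0 h baseline within a subset,
or CD4 against CD8 within a timepoint.

## Preprocessing

**Protein QC.** A protein is retained iff it has >= 2 unique/razor peptides,
an identification score >= 5, and < 20% missing values across all samples
jointly (not per group — the filter describes dataset-level identification
quality, not testability). Missing intensities are explicit (`NA`), never
zero; a `zeros_are_missing` reader flag converts legacy tables that encode
non-detection as 0. No imputation is performed anywhere: the test layer
handles missingness by omitting absent values and refusing to test features
with fewer than two present values per group.

**mRNA normalization.** Counts are converted to log2(CPM + 1) on effective
library sizes, i.e. raw column sums scaled by TMM factors. The TMM
implementation follows the edgeR algorithm: reference column = the one whose
upper-quartile CPM is closest to the mean upper quartile; gene-wise log
ratios (M) and mean log abundances (A) over genes positive in both samples;
double trimming (30% on M, 5% on A, rank-based); factor = 2^(precision-
weighted mean of retained M) with inverse approximate binomial variances as
weights; factors rescaled to geometric mean 1. Note that because the weights
are count-level precisions, TMM factors are invariant to rescaling a column
only asymptotically (the tests assert agreement within 2% under a 3x column
rescale, and exact agreement with an independent from-scratch implementation
on fixed fixtures). Protein intensities are assumed already normalized
upstream (maxLFQ) and are only log2-transformed.

**Fold changes** are differences of group means on the log2 scale (mean of
logs, not log of means), with missing values omitted per group.

## Differential expression

Each feature is tested by an unpaired two-sample t-test with pooled
(equal-variance) SD; two-sided p from the t distribution with nA + nB - 2
df. A paired-by-replicate mode exists behind a flag for donor-matched
designs. Degenerate rows are defined, not dropped: zero pooled variance with
equal means gives p = 1; zero variance with different means gives p = 0 and
an infinite statistic. Features with < 2 present values in either group are
untested (`tested = False`) and never enter the FDR correction.

**Two-stage FDR (Benjamini–Krieger–Yekutieli).** Stage 1 runs
Benjamini–Hochberg at q' = q/(1+q), yielding r1 rejections; r1 = 0 rejects
nothing, r1 = m rejects everything, otherwise stage 2 is BH at
q'·m/(m − r1). The reported q-value of a feature is the *smallest nominal q
at which the two-stage procedure rejects it*, computed exactly by scanning
the intervals of q on which the stage-1 count is constant (the stage-1 count
is a step function of q with breakpoints where q/(1+q) crosses a distinct
BH-adjusted p-value). This definition guarantees that thresholding the
q-values at any level reproduces the procedure's rejection set exactly —
a property the tests assert, alongside agreement of the rejection mask with
statsmodels' independent `fdr_tsbky` implementation and Monte-Carlo FDR
control (empirical FDR <= nominal within 3 MC standard errors at q = 0.05,
power >= plain BH).

**DE calls** combine fold change and significance with the layer-specific
conventions: mRNA is DE iff |log2fc| > 1.5 (strict) and q < 0.01 (strict);
protein is DE iff |log2fc| >= 1.0 (inclusive) and q <= 0.05 (inclusive).
The strict/inclusive asymmetry is deliberate and boundary-tested. Percent-DE
is 100 x (DE features / quantified features) per contrast.

## Coupling analysis

Protein and gene universes are joined through an explicit ID map; a protein
mapping to several genes contributes one pair per mapping (flagged), with a
best-single-mapping mode behind a flag. Per timepoint, the Pearson
correlation r is computed over the (mRNA log2fc, protein log2fc) of matched
pairs whose *transcript is DE at that timepoint* — the default selection;
"DE at any timepoint" and "all pairs" are selectable alternatives since the
gating convention is a genuine design choice. r requires >= 3 pairs and is
otherwise reported missing. Strength bands on |r|: strong >= 0.70 >
moderate >= 0.40 > weak >= 0.10 > negligible. Quadrant summaries classify
pairs by the signs of the two fold changes; pairs with an exactly-zero fold
change on either axis are excluded (tie rule) so fractions sum to 1. The
lag track anchors on transcripts DE at 6 h and counts, per timepoint, how
many of their proteins are DE (up/down, plus the cumulative count DE at
>= 1 timepoint so far) — the cumulative series is non-decreasing by
construction.

## Kinetic clustering

Features DE at >= 1 timepoint enter a fold-change profile matrix (0 h
column fixed at exactly 0 so all profiles share an anchored origin), which
is z-scored per row; zero-SD rows are dropped with a log entry. Fuzzy
c-means follows the Bezdek alternating updates (Euclidean distance,
membership u_ik = 1/sum_j (d_ik/d_ij)^(2/(m−1)), centroids as u^m-weighted
means), with the singularity rule that a point coincident with a centroid
takes full membership there. The fuzzifier m defaults to the
Schwämmle–Jensen estimate from the data dimensions, clipped to [1.05, 3].
Initialization is a seeded k-means++-style draw from the profile rows;
`n_init = 5` independent restarts are run and the solution with the lowest
final objective kept, guarding against merged-cluster local optima. The
cluster count defaults to c = 12 with no automatic model selection. Core
members are features whose maximum membership is >= 0.5 with a unique
argmax (exact ties break "not core"). The estimator (`FuzzyCMeans`) follows
the scikit-learn fit/predict/transform contract and composes with sklearn
tooling. Hierarchical profile clustering uses average linkage on
1 − Pearson distance; constant profiles are dropped.

Because fuzzy c-means is not reproducible run-for-run across software, the
validation is by planted-archetype recovery (ARI >= 0.9 on core members),
membership normalization, and objective monotonicity — never by comparing
cluster identities to an external run.

## Over-representation analysis

One-sided hypergeometric tail p = P(X >= k) for the overlap k of a query
set with each gene set, inside a background universe defaulting to all
quantified features of the relevant layer after QC (not the genome);
Benjamini–Hochberg FDR across sets (deliberately the plain BH, not the
two-stage procedure — both corrections coexist in the package and serve
different steps). Sets are intersected with the background before testing;
depletion is out of scope.

## The synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which the analysis is validated.

**Kinetics.** Transcript induction is the simplest monotone family that
reproduces early-transcript/late-protein behavior: M(t) = B(1 + (F−1)s(t)),
s(t) = 1 − exp(−max(0, t−t_on)/tau_m); down-regulation uses F < 1 with the
same form. Protein follows dP/dt = k_s M(t) − k_d P from the
pre-stimulation steady state P(0) = k_s B/k_d, evaluated with the piecewise
closed form of the linear ODE (expm1 formulation, stable in the
k_d = 1/tau_m degenerate limit; verified against stiff-safe numerical
integration to 1e-6 relative). First-order degradation makes the protein
half-rise provably lag the mRNA half-rise — the mechanism behind the
early-uncoupling/late-coupling pattern the coupling module measures.

**Defaults and why** (chosen once as the emulated study's conditions):

| parameter | default | rationale |
|---|---|---|
| n_genes | 2000 | desk-scale stand-in for a ~11k-transcript matrix |
| protein_fraction | 0.2 | ~20% of transcripts quantified at the protein level |
| de_fraction | 0.10 | planted responder fraction (200/2000) |
| subset_de_fraction | 0.025 | constant between-subset effects (50/2000), log2 magnitude 2.5–4.5 |
| responder plateau &#124;log2 F&#124; | U(2.5, 5) | strong receptor-driven induction |
| archetype mix | 30/10/10/30/10/10% | immediate-early wave dominates; onsets 0/12/48 h, tau 4/12/36 h, up and down |
| nb_dispersion | 0.02 | donor-matched sorted cell populations; shared across genes (adequate for n = 3 testing) |
| library_size_mean, cv | 1e6, 0.15 | sequencing-depth variation |
| intensity_cv | 0.25 | label-free DDA intensity noise |
| missing_rate, mnar_weight | 0.10, 0.5 | half the missingness mass concentrated in the lowest-intensity tercile |
| k_s | logU(0.05, 0.5)/h | translation rate (scale cancels in fold changes) |
| k_d | logU(0.002, 0.03)/h | protein half-lives ~1–14 days; slow turnover is the lag |
| qc_fail fractions | 0.05 each | planted 1-peptide, low-score, and high-missingness proteins so every filter fires |

Peptide counts are 2 + Poisson(7) (planted failures: 1) and identification
scores U(5, 20) (planted failures: U(0, 5)).

**What the generator does not emulate:** per-gene dispersion, batch and
run-order effects, transient (up-then-down) transcript kinetics in the
dataset generator (the clustering test archetypes do include transient
shapes), protein-level regulation beyond first-order turnover
(post-translational modification, complex-partner stabilization), and
peptide-level detail. Passing recovery tests therefore demonstrates that
the machinery is correct under its stated model, not that the thresholds
are optimal for any particular real dataset.

## Orchestration and reproducibility

A single global seed fans out to per-stage seeds by fixed offsets, so each
stage is independently reproducible. Every result is written as TSV with a
canonical JSON run report (sorted keys, no timestamps); two runs with the
same config and seed produce byte-identical reports. The report's internal
count constraints (post-QC + excluded = quantified; DE <= tested <=
quantified; non-decreasing lag counts) are asserted on every run, not just
documented. In synthetic mode the pipeline also emits a gene-set collection
built from the planted archetype memberships plus random decoys so the
enrichment stage runs end-to-end against known structure.

Problem sizes used in the shipped validation (2000 genes, 600 proteins,
36 samples per layer; 500 Monte-Carlo replicates for FDR operating
characteristics; 600 profiles for clustering recovery) were chosen so the
full suite and the acceptance script each complete in well under a minute
of compute while leaving the recovery margins wide.

## Known limitations

- The t-test route uses no variance moderation (no empirical-Bayes
  shrinkage); with n = 3 this is deliberately conservative and features
  with unlucky variance draws near the effect threshold can be missed at a
  single timepoint. Detection is therefore best read at the time-course
  level (DE at >= 1 timepoint).
- TMM scale invariance is asymptotic (see above).
- Correlation kinetics at early timepoints rest on few pairs when few
  transcripts are DE; r is suppressed below 3 pairs but remains noisy at
  small n — the generator's early-responder weighting keeps the 6 h pair
  count high enough for the qualitative pattern to be stable.
- One-to-many ID mappings default to contributing multiple pairs, which
  double-counts proteins in correlation estimates when maps are ambiguous;
  use best-single mode for heavily redundant maps.
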