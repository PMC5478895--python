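# Methods

This note documents the models, defaults and numerical choices behind
factoromics, and what the synthetic study generator does and does not
emulate.

## Factorial linear model and moderation

Every abundance layer is modelled per feature on the log2 scale as

    expr = β0 + β_Nlim·x_Nlim + β_DGA·x_DGA + β_DGAxNlim·x_DGA·x_Nlim + ε,

a saturated parameterization of the 2×2 design: β0 is the control-strain,
carbon-limited baseline, the two main effects are log2 fold changes, and the
interaction is the departure from additivity. With 12 samples and 4
parameters each fit has 8 residual degrees of freedom.

RNA counts enter as log2 CPM, `log2((count + 0.5)/(lib·f + 1)·1e6)`, with
prior count 0.5 and offset 1.0; `f` are TMM factors computed against the
library whose upper-quartile CPM is closest to the mean upper quartile,
double-trimming 30 % on M and 5 % on A and weighting retained M values by
inverse asymptotic binomial variance, then rescaling to geometric mean 1.
The trim fractions and the trimming-by-rank convention follow the original
TMM formulation; the implementation agrees with an independent
reimplementation of the definition to 1e-8 in the tests.

Residual variances are moderated with a scaled-inverse-χ² prior whose
hyperparameters (d₀, s₀²) come from moment matching on log s²: the inverse
trigamma is solved by Newton iteration, and numerically-zero variances
(constant features) are excluded from the matching because their log
variances are floating-point noise. Moderated t uses d₀+d degrees of
freedom; when the observed spread of log s² is below the χ² sampling floor
the prior df is infinite and the normal reference is used. Moderation can be
disabled (`fit(moderate=False)`), which reproduces ordinary least-squares t
statistics exactly.

Optional voom-style precision weights (inverse fourth power of a lowess
trend of √SD on mean log count) are implemented but off by default: the
moderated-t path on plain log-CPM is the primary analysis surface, and the
weights are an option flag for data with a strong mean–variance trend.

Multiple testing is Benjamini–Hochberg per coefficient across features
(delegated to statsmodels, verified against a brute-force step-up oracle).
Directional adjusted P values are sign(β)·adjusted P. Two significance
thresholds appear downstream: 0.05 for differential-expression summaries and
0.01 for the clustering and correlation subsets.

Protein matrices re-enter this identical pipeline after rollup (values are
already log2; `FactorialDE.from_dataframe`), and metabolite intensities
enter as log2 of the reported intensity. Condition-pair comparisons (e.g.
DGA1 vs control under nitrogen limitation) use `results.contrast(c)` with
the exact unscaled covariance of the fit, e.g. c = (0, 0, 1, 1).

## Factor-order clustering

Significant genes (minimum of the three non-intercept adjusted P < 0.01)
are labelled by the descending order of their three *signed* coefficients.
Signed values — not |β| and not standardized β — are ranked because the
clusters are meant to read as regulatory patterns ("nitrogen limitation up,
interaction down"), which only signed ordering expresses. Exact ties fall
back to the fixed priority N > D > D×N and are flagged. There are exactly
six clusters; empty ones are reported with count 0.

## Consensus gene-set analysis

Sets are first restricted to the analysis universe and size-filtered
(fewer than 5 or more than 500 members discarded). Three set statistics are
computed per set: mean t, median t, and the Stouffer combination of
one-sided P values. The null is gene-label permutation — with 12 samples
there are too few sample permutations to be useful — with P = (1+b)/(B+1)
for B draws, or exact enumeration over all same-size subsets when requested
(`n_perm=None`, capped at 200,000 subsets). Four directionality classes are
reported: distinct-up (upper tail of the signed statistic), distinct-down
(lower tail), mixed (two-sided, 2·min(up, down)), and non-directional
(upper tail of the |t| statistic). The "mixed" rendering is this package's
concrete choice for a class that the field's tooling defines in several
inequivalent ways. The consensus rank score is the median of a set's three
per-method ranks within a class; it is invariant to the order in which the
methods are supplied because the median ignores order. Typical reporting
cutoffs are 1 (strict) or 5 (loose).

Hypergeometric over-representation of a gene list uses the one-sided upper
tail P(X ≥ k) with BH across sets; it is checked against exhaustive
enumeration for universes up to 12 genes.

## Discriminative motif search

Candidate words are all distinct 3–8-mers present in the positive promoter
set, canonicalized across strands (a word and its reverse complement are
one candidate; a sequence "contains" a word if either strand matches).
Scoring uses sequence containment — one count per sequence regardless of
site multiplicity — in a one-sided Fisher exact test of positives vs
controls. The best word is greedily generalized by single-position IUPAC
substitutions (up to 4 rounds, expansion capped at 4096 exact words),
accepting a substitution only when the Fisher P strictly improves. The
E-value is the final P times the number of exact candidate words evaluated
in that pass; generalization steps do not inflate the candidate count.
Motifs with E below the cutoff (default 10⁻³) are reported, their sites
erased (replaced by a non-alphabet character that breaks words), and the
search repeats. Ties between equally significant words break
lexicographically, making the output deterministic and invariant to input
sequence order. The PWM of a reported motif is built from all matching
sites in the positive set with pseudocount 0.25 per base.

Reference matching is deliberately lightweight: best ungapped offset
alignment over both strands, scored by the mean per-column Pearson
correlation (minimum overlap 4 columns), reporting matches above 0.8. It
answers "which known motif does this resemble" without a match-null model.

Per-cluster runs use the cluster's promoters as positives and the promoters
of all other genes as controls.

## Proteomics rollup and transcript–protein correlation

Peptides observed in fewer than half the samples are removed. Per-sample
offsets are estimated from rank-invariant peptides: complete-case peptides
whose abundance rank moves by less than 10 % of the complete-case count
across all samples; the offset is the median deviation of those peptides
from their across-sample means, with a global-median-centering fallback
(warned) when none qualify. Rollup picks, per protein, the most frequently
observed peptide as reference (ties toward the higher median), shifts every
other peptide by the median of its per-sample log2 difference to the
reference, and takes the per-sample median of shifted peptides. The
protein profile is therefore anchored at the reference peptide's level;
the anchor cancels in everything downstream (Pearson correlation and GLM
factor effects are shift-invariant), so only profile shape matters.

Correlation is computed only for genes observed in all 12 samples on both
platforms. Per gene, Pearson r with the two-sided P from the t transform
with n−2 df; the pooled all-pairs r and the r distributions stratified by
differential expression (adjusted P < 0.01 at the transcript level) are
summarized, and the highly correlated list (correlation P < 0.01) feeds
hypergeometric enrichment.

## Flux sampling and regulation scores

The toy stoichiometric model has 14 reactions and 11 metabolites: a
glycolysis surrogate (glucose → 2 pyruvate + 2 ATP), a pyruvate
dehydrogenase step, a TCA surrogate (acetyl-CoA + 2 O₂ → 2 CO₂ + 10 ATP), a
lipid branch (8 acetyl-CoA + 7 ATP → lipid), a leucine-like branch
(2 pyruvate + acetyl-CoA → IPM → leucine) with an IPM exchange, protein
synthesis from leucine, a biomass reaction consuming protein, lipid and
ATP, a non-growth maintenance ATP drain, and glucose/O₂/CO₂/IPM/biomass
exchanges. Units are mmol gDW⁻¹ h⁻¹ (biomass in h⁻¹); exchanges are written
metabolite → ∅ so uptake is negative. GPR strings are boolean gene
expressions; AND resolves a reaction to its minimum-|z| member (a complex
is limited by its weakest-changing subunit), OR to the maximum (the
strongest isoenzyme signal).

Condition constraints bound each measured exchange and the growth rate to
mean ± 1 SD (configurable multiplier) and rewrite the biomass reaction's
protein and lipid coefficients to the condition's measured composition.
Infeasibility is diagnosed by single-constraint relaxation and reported
with the culprit reactions. The maintenance drain is then maximized by LP
and restricted to [0.95·max, max], the closed interval below its optimum.

Sampling is artificial-centering hit-and-run: 100 warm-up vertices from
LPs with standard-normal random objectives, directions drawn as (random
warm-up point − running center) projected onto an orthonormal null-space
basis of S, step lengths uniform over the feasible chord, thinning 10 by
default. Each recorded draw is re-projected onto the equality manifold
(pseudoinverse correction) and clipped to bounds, keeping |S·v| at machine
precision. A stoichiometric matrix with condition number above 1e12 across
its retained singular values is rejected with a diagnostic; a polytope
whose warm-up points coincide (fully determined network) returns the unique
point with zero spread. Draws are deterministic given (model, n, seed).

Cross-condition flux change is Z = (μ_a − μ_b)/√(σ_a² + σ_b²) with an SD
floor of 1e-12 and Z = 0 when both spreads and the mean difference vanish;
the statistic is exactly antisymmetric. The regulation score of a
reaction–gene pair is sign·min(|Z_flux|, |z_RNA|, |z_protein|) when the
three signs agree and 0 otherwise, with |score| > 2 called
transcriptionally regulated. This sign-concordant minimum is the package's
concrete rendering of flux–expression correlation scoring: it is
deliberately conservative (a pair scores only as high as its weakest
level), and the threshold mirrors the convention that sampled-flux Z
scores become meaningful above about 2.

## Synthetic study generator

The generator emulates the data layers of a triplicate 2×2 chemostat study
(12 samples) with known ground truth:

* **RNA**: counts ~ NB(mean = lib·2^(Xβ)/Σ, variance μ + φμ²), φ
  log-uniform on [0.01, 0.5] — the variability range consistent with
  triplicate RNA-seq — and library sizes lognormal around 2×10⁶ (desk
  scale, far below real depths). Six planted clusters (20 genes each by
  default) realize the 3! orderings of signed contributions with ranked
  values (+2.0, +0.5, −1.5) plus ±0.1 jitter; margins ≥ 1.3 log2 keep the
  orderings identifiable at triplicate noise. The remaining 480 genes are
  null. Two genes of the N>D>DxN cluster are overridden to (+0.5, −1.5,
  −2.5) with minimal dispersion: they are the leucine-branch genes of the
  metabolic model, giving the strong concordant down-shift in the DGA1 vs
  control contrast under nitrogen limitation (c = (0,0,1,1), effect −4
  log2) that the regulation-score stage is meant to recover. A
  `plant_pathway=False` switch produces a genuinely global-null study.
* **Proteins**: 60 % of genes are "measured"; coupled genes follow
  translation_efficiency·CPM with lognormal noise (σ = 0.3 log2), a 10 %
  decoupled subset gets RNA-independent lognormal profiles. Proteins
  shatter into 2–8 peptides with lognormal response factors, peptide-level
  noise (σ = 0.25 log2) and 10 % missingness, exercising the QC filter.
* **Metabolites**: 30 lognormal intensities; an IPM-like intermediate
  carries (+1.5 N, −2.0 D×N) effects and a mannitol-like carbohydrate +2.0
  on N, the pattern of an overflow metabolite suppressed by the
  interaction.
* **Promoters**: 600 bp uniform-background ACGT (no real promoter length
  is canonical; 600 bp is a plausible regulatory window). One 8-mer per
  cluster is planted in 80 % of members at a uniform position; all other
  promoters are redrawn until they contain no planted word on either
  strand. Planted words are 8-mers because at 600 bp the chance that a
  random promoter contains a given short word is large (≈25 % for 6-mers
  vs ≈2 % for 8-mers), which would dilute containment-based discrimination
  at this scale.
* **Gene sets**: one coherent 12-gene set per cluster plus 10 random
  background sets, as GMT.
* **Physiology and model**: per-condition exchange measurements are taken
  from a closed-form reference flux state of the toy network (growth 0.048
  h⁻¹, glucose uptake 0.62–0.68, per-condition lipid/protein biomass
  coefficients, IPM excretion 0.1 under nitrogen limitation alone and
  ≈0 with the genetic perturbation), with fixed small SDs. Constraining
  the model to these measurements is therefore feasible by construction,
  and the planted leucine-branch shift between conditions is known
  exactly.

Everything is drawn from one seeded generator: identical (config, seed)
bundles are bit-identical, including their serialized files.

What passing tests on this generator do **not** show: the NB dispersions
and library depths are not calibrated to any real study; promoters have no
compositional structure (GC bias, repeats) so motif discrimination is
easier than on genomic sequence; peptide missingness is independent rather
than intensity-dependent; the toy network's polytope is far more
constrained than a genome-scale model, so sampled flux SDs are optimistic;
and real transcript–protein coupling is weaker and more structured than
the lognormal model used here.

## Problem sizes and numerical choices

Default analyses and the acceptance script run at 600 genes, 2,000 flux
draws per condition (50,000 for the analytic sampler calibration, where
one draw is one chain step), 20 permutation seeds for calibration rates,
and 20 independent studies for motif recovery — sizes chosen so the full
validation cycle completes in minutes on a laptop while keeping Monte
Carlo error well inside the asserted tolerances. Other fixed choices:
Fisher/hypergeometric tails go through scipy's survival functions; the
glucose molar mass is fixed at 180.16 g/mol for the yield conversion;
yields and RQ round to 2 decimals for presentation; BH monotonicity is
enforced by the step-up running minimum; and the ACHR safety net aborts if
ten times the requested steps fail to produce the requested draws.

## Known limitations

The motif search enumerates exact words and generalizes greedily — it will
miss motifs whose instances never share an exact core word. The consensus
GSA reduces the method roster to three statistics; rank scores are not
comparable across universes of different sizes. The rollup anchors protein
profiles at the reference peptide, so absolute protein levels are not
interpretable, only profiles. Flux Z-scores inherit the polytope's width:
with few measured exchanges the sampled SDs are large and the score is
conservative, under-reporting genuinely regulated fluxes — a property of
the approach, not a bug of the implementation.
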