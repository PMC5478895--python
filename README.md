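# factoromics

Multifactorial multi-omics regulation analysis for 2×2 factorial chemostat
studies.

The package addresses a recurring systems-biology question: when a genetic
perturbation (e.g. overexpression of the diacylglycerol acyltransferase gene
*DGA1* in an oleaginous yeast) and an environmental condition (nitrogen vs
carbon limitation) jointly change a phenotype such as lipid accumulation,
*which layer of regulation carries the change*? It integrates RNA-seq counts,
label-free proteomics, metabolite intensities and constraint-based flux
estimates from one factorial design, and scores where transcript, protein
and flux shift together. It is written for computational biologists who have
the per-layer measurement matrices in hand and want a tested, reusable
pipeline from counts to regulation calls — including a synthetic study
generator with complete ground truth, so every stage can be validated
without access to any real data set.

## The model

Each feature's log2 abundance is described by a general linear model over
the two binary factors and their interaction:

```
expr_g = β0 + β_Nlim·x_Nlim + β_DGA·x_DGA + β_DGA·Nlim·x_DGA·x_Nlim + ε
```

RNA counts are filtered (kept when >1 CPM in ≥3 libraries), scaled with
trimmed-mean-of-M-values (TMM) factors, log2-CPM transformed, and fitted
feature-wise by least squares. Residual variances are shrunk with an
empirical-Bayes scaled-inverse-χ² prior (moment matching on log s²), giving
moderated t statistics with d₀+d degrees of freedom; P values are
Benjamini–Hochberg adjusted per coefficient. Protein and metabolite matrices
go through the identical model class.

Downstream of the fit:

* **Factor-order clusters** — significant genes (adjusted P < 0.01) are
  grouped by the descending order of their three signed coefficients
  (3! = 6 clusters), e.g. `N>D>DxN` for genes pushed up by nitrogen
  limitation and down by the interaction.
* **Gene sets** — hypergeometric over-representation, and a consensus
  gene-set analysis: three set statistics (mean t, median t, Stouffer)
  under four directionality classes with a gene-label permutation null;
  the consensus rank score is the median rank across statistics.
* **Promoter motifs** — a discriminative word search over each cluster's
  promoters against all other promoters: Fisher exact tests on sequence
  containment, greedy IUPAC generalization, E-value = best P × number of
  candidate words, cutoff 10⁻³; found PWMs are matched to a reference
  collection by best ungapped alignment correlation.
* **Proteomics rollup** — peptide QC (≥50 % observed), rank-invariant
  per-sample normalization, reference-based rollup to protein profiles,
  and per-gene Pearson correlation of transcript vs protein across the 12
  samples (restricted to genes with complete dual-platform coverage).
* **Flux regulation** — a stoichiometric model is constrained per condition
  (measured exchanges and growth within ±1 SD, biomass recomposed to the
  measured lipid/protein coefficients, maintenance ATP restricted to a 5 %
  window below its LP maximum), its flux polytope is sampled with
  artificial-centering hit-and-run, cross-condition changes are summarized
  as Z = (μ_a − μ_b)/√(σ_a² + σ_b²), and each reaction–gene pair with
  sign-concordant flux, transcript and protein changes receives the
  regulation score sign·min(|Z_flux|, |z_RNA|, |z_protein|); |score| > 2 is
  called transcriptionally regulated.

## Worked example

```python
from factoromics import FactorialDE, rank_factor_contributions
from factoromics.synthetic import SimulationConfig, generate_study

bundle = generate_study(SimulationConfig(), seed=7)
fits = FactorialDE.from_counts(bundle.counts, bundle.design).fit()
print(fits.summary())
```

```
Factorial differential expression (2x2, interaction model)
  features: 600    samples: 12
  residual df: 8    prior df: 2.34    posterior df: 10.3
  significant features (BH adj P < 0.05) per factor:
         Nlim:    66  (35 up, 31 down)
          DGA:    69  (36 up, 33 down)
     DGAxNlim:    50  (27 up, 23 down)
```

600 simulated genes were fitted on 12 samples; the variance prior adds 2.34
effective degrees of freedom to each gene's 8 residual df. Of the 120 genes
simulated with non-null effects, 66/69/50 are recovered per factor at
adjusted P < 0.05 at this depth and replication. Clustering the significant
genes by factor-contribution order,

```python
assignment = rank_factor_contributions(fits, alpha=0.01)
print(assignment.attrs["cluster_sizes"].to_string())
```

```
N>D>DxN    15
N>DxN>D    17
D>N>DxN    14
D>DxN>N    15
DxN>N>D     9
DxN>D>N    14
```

recovers all six planted coefficient orderings. The same bundle carries
promoters with planted motifs, peptide tables, metabolite intensities, a toy
metabolic model and per-condition physiology; `factoromics --help` lists the
command-line entry points for each stage (`simulate`, `diffexpr`, `cluster`,
`gsa`, `motifs`, `correlate`, `flux`, `yields`).

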