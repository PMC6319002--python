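# Methods

## Model

For every response (a gene's log2-cpm vector or a phenotype) the pipeline fits
the single-kernel animal model

    y = X b + a + e,   a ~ N(0, σ²ₐ G),   e ~ N(0, σ²ₑ W),

with `G = Z Z'` the genomic relationship matrix built from dosages centered at
twice the reference-allele frequency and scaled once, globally, by
`√Σⱼ 2pⱼ(1−pⱼ)`. Allele frequencies are computed from the analyzed animals.
`W` is `w_std[g]·I` for gene g (one scalar per gene, because the mean–variance
trend is estimated from per-gene summaries) and `I` for phenotypes.

Variance components are estimated by REML. The eigendecomposition `G = UΔU'`
is computed once and shared across all responses; for each response the
restricted likelihood is profiled over the variance ratio λ = σ²ₐ/σ²ₑ (a
25-point log-spaced grid bracketing a bounded Brent refinement on
λ ∈ [1e-6, 1e6]), so the per-response cost after setup is O(n) per likelihood
evaluation. The σ²ₐ = 0 boundary is always evaluated explicitly, which
guarantees logL_full ≥ logL_null. A scalar residual weight only rescales σ²ₑ
and is folded out analytically; vector weights (supported but not used by the
default pipeline) whiten the data by W^{−1/2} and decompose the whitened G.
ML is available via `method="ml"`; REML is the default because the halved-χ²₁
reference for the boundary LRT is standard for REML variance components.

Heritability is h² = σ²ₐ/(σ²ₐ+σ²ₑ) with the residual weight *not* folded into
the ratio. Its significance comes from LR = 2(logL_full − logL_null) clipped
at zero, with p = ½·P(χ²₁ ≥ LR): under the boundary null the LR is
asymptotically a 50:50 mixture of a point mass at zero and χ²₁, so LR = 0
yields p = 0.5 exactly.

## Backsolve GWAS

Writing P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹ for the projection at the REML
estimates, the marker effects backsolved from the breeding values are
`ĝ = σ²ₐ Z'Py` with `Var(ĝ)ⱼ = σ⁴ₐ (Z'PZ)ⱼⱼ` (this equals
`Z'G⁻Var(â)G⁻Z` with `Var(â) = σ⁴ₐ GPG`, the predictor variance
σ²ₐG − PEV). The standardized statistic `T = ĝ/√Var(ĝ)` is algebraically
identical to the GLS test of each marker fitted as a single fixed effect at
the same variance components; the test suite asserts |Δlog10 p| < 1e-6
against that oracle on every marker. Components are *not* re-estimated per
marker. Markers with zero effect variance (e.g. constant after conditioning)
are assigned T = 0, p = 1. G is decomposed with an explicit PSD check; all
computations run in the eigenbasis, so rank deficiency (m < n, duplicated
animals) is handled without forming an inverse.

Per-gene FDR is Benjamini–Hochberg over the concatenated p-values of all the
gene's transcripts across all markers. eQTL records group significant markers
(FDR ≤ 0.01) by chromosome; the interval spans the first to last significant
marker with no gap-splitting (wide intervals are expected under F2 LD), and
multiple peaks arise only through the conditional scan, which refits with the
peak SNP as a covariate and re-applies BH to that chromosome's markers. Peak
ties break by (min q, min p, leftmost position).

## Regulator classification

Class is decided from the *full* marker map, including markers removed by MAF
or LD pruning (their positions were genotyped even though they carry no
statistic): different chromosome → distant; closed-interval overlap with the
gene span (partial counts) → local; otherwise any marker strictly between the
gene span and the interval → distant-same-chromosome; else plausible-local.
"Strictly between" uses the open gap between the two closed intervals, so a
marker exactly at a gene edge or interval edge does not block plausible-local.
A `kept_only` switch restricts the intervening-marker test to analysis
markers; this can only move calls from distant-same-chromosome to
plausible-local, never the reverse. eQTL–gene distance is the peak-to-nearest
gene-edge distance in Mb (zero if the peak lies inside the gene; undefined
across chromosomes).

## Co-localization

pQTL are mapped with identical machinery at FDR ≤ 0.05 and unit weights.
Overlapping (same chromosome, closed intervals intersecting) eQTL/pQTL pairs
are tested conditionally: the pQTL peak dosage, standardized by its own
sample mean and sd (distinct from the global GRM scaling), enters as a fixed
covariate, the variance components are refit under this conditional model,
and `b_SNP` gets a Wald test from the GLS coefficient covariance at the REML
optimum. Significance requires both the Bonferroni cutoff 0.05/n_tests
(n_tests = conditional tests actually run in the batch; 84 tests reproduce
the 5.952e-4 cutoff) and complete elimination: no marker inside the original
eQTL interval significant at FDR ≤ 0.01 after conditioning (a `genomewide`
switch tightens this to the whole genome). The SNP variance is
σ²_SNP = b²·var(Z_SNP) and proportions divide by σ²_SNP + σ²ₐ + σ²ₑ from the
conditional fit, making them invariant to rescaling y.

## Synthetic data generator

The generator emulates a two-line F2 design: line-A sires and line-B dams
(defaults 4 and 15), an F1 pool (56), and F2 offspring of random distinct F1
pairs. A configurable fraction of markers (default 0.3) is fixed for
alternate alleles between lines; the rest segregate at a shared U(0.1, 0.9)
frequency. Meiosis is Haldane: crossover counts Poisson in map length,
positions uniform, no interference — chosen because the F2 dosage correlation
has the closed form e^(−2d) at distance d Morgans, giving an enumerable LD
oracle. Founder-line origin is tracked per F2 haplotype for diagnostics.

Expression is negative-binomial with a log-scale latent trait: a causal-marker
effect, a polygenic term `Z u` (u iid normal, making h² well defined under the
globally-scaled GRM), and Gaussian noise, each rescaled so realized variance
fractions equal `h²·cf`, `h²·(1−cf)` and `1−h²` of `latent_sd²` (defaults
cf = 0.7, latent_sd = 0.5 — roughly two-fold biological expression variation).
Counts are gamma-Poisson around `base_g · depth_i · exp(latent)`; dispersion
(default 0.01) represents *technical* overdispersion only, since biological
variability is already carried by the latent residual; per-sample depth is
lognormal (sd 0.15). Mean library size (default 3e5 across 300 genes, ~1000
counts per gene) keeps counting noise realistic for desk-scale panels.
Phenotypes are sex effect + optional causal marker + polygenic + error with
exact variance fractions; flagged traits reuse a designated gene's causal
marker to plant co-localization truth. An optional two-tail-selection switch
is exposed but off by default: selective transcriptional profiling enters the
analysis only as a fixed covariate, so random sampling is the default study
condition. Hotspot targets all share one designated marker.

Heritability-recovery simulations draw traits directly on the latent Gaussian
scale (`y = Zu + e` with the realized variance split exact), i.e. the scale on
which h² is defined; the count → TMM → log-cpm path is exercised separately by
the end-to-end recovery studies.

## Normalization details

TMM uses the canonical published trims (M 30%, A 5%, both configurable),
inverse asymptotic-variance weights, a reference sample chosen by the
upper quartile of nonzero cpm closest to the mean, and factors rescaled to
geometric mean 1 (cross-checked against edgeR during development; agreement
to ~4 decimals, the residue coming from reference-quartile details).
log-cpm uses the standard +0.5 count / +1 library offsets. The mean–variance
trend is a LOWESS fit (span 0.5, 3 robustifying iterations) of per-gene
residual sd against mean log-cpm after an OLS fit on the fixed-effect design;
the squared trend value is the per-gene variance ŵ, and the standardized
coefficients divide 1/√ŵ by its mean **over genes** — the only reading under
which the coefficients have unit mean and keep residual and additive variance
on similar scales. The displayed error distribution e ~ N(0, σ²ₑ·diag(w_std))
is implemented as written; an inverse-weight switch is exposed for the
alternative reading.

## Study conditions for the recovery simulations

Recovery studies (classification, hotspot, co-localization, pQTL power) use
n = 400 F2 animals on an 18-autosome genome with 40 markers per 100-cM
chromosome and a 150-gene expression background. Two properties of small toy
genomes motivated these sizes, both identified during development: (i) with
few chromosomes each LD block is a large fraction of the genome, and the
mixed model absorbs a planted marker effect into the polygenic term (proximal
contamination), understating the power the method has on a realistic
karyotype; (ii) with few simulated genes, a marker driving many of them
leaks into the library size and cpm normalization subtracts the planted
signal — a compositional artifact absent at realistic gene counts. Planted
effects follow the study design: local/distant genes h² = 0.4 with 70% of
genetic variance at the causal marker, hotspot targets h² = 0.5 at one shared
marker (12 genes), co-localization pairs a single-QTL gene (h² = 0.15, all of
it at the causal marker) with a phenotype whose same marker explains 15% of
variance over a 0.2 polygenic background.

## Numerical choices and degenerate inputs

Eigenvalues of G are floored at zero after a PSD check (tolerance 1e-8 times
the largest); λ is searched on [1e-6, 1e6] with boundary hits flagged in fit
metadata. With G = I the additive/residual split is unidentifiable: the fit
reports the correct total variance and an arbitrary boundary split, which the
tests document rather than hide. All-zero count samples, constant phenotypes,
constant conditioning SNPs, empty marker panels and rank-deficient designs
raise or warn explicitly. Wilcoxon rank-sum uses exact enumeration for
untied samples with both groups ≤ 20 and the tie-corrected normal
approximation otherwise (exact enumeration with ties is not defined in the
backend). BH q-values come from statsmodels; Fisher's exact test and the
rank-sum statistic from scipy.

## Limitations

Single additive kernel only (no dominance GRM or multi-kernel models); no
missing genotypes (imputation is out of scope); X-chromosome inheritance and
sequence-level simulation are not modeled; the generator plants at most one
causal marker per gene (two-QTL behavior is exercised with directly
constructed latent traits); hotspots are detected by the counting rule only,
with no multiplicity control beyond the per-gene FDR. Passing recovery tests
on synthetic data shows the machinery is correct under the generator's
assumptions (Haldane meiosis, NB counts, additive architecture); it does not
certify performance on real data with selection, family structure beyond the
simulated pedigree, or expression networks.
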