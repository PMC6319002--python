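# eqtlcross

Mapping the genetic control of gene expression in an F2 intercross, and asking
which expression QTL (eQTL) share their signal with organismal phenotype QTL
(pQTL).

F2 resource populations — two divergent founder lines crossed to F1 and then
intercrossed — are a workhorse design in livestock genetics, but their
long-range linkage disequilibrium defeats the fixed cis-distance cutoffs used
in human eQTL scans. `eqtlcross` implements an LD-aware alternative as a
tested, reusable pipeline:

1. **Preprocessing** — marker filtering (monomorphic, MAF < 0.01, adjacent
   dosage correlation > 0.95), TMM normalization of RNA-seq counts, log2-cpm
   transformation, and a LOWESS mean–variance trend giving one standardized
   variance coefficient per gene,
   `w_std_g = (1/√ŵ_g) / mean(1/√ŵ)`, so heteroskedastic residual variance
   enters the mixed model on a common scale.
2. **Weighted GBLUP** — per trait, `y = Xb + a + e` with
   `a ~ N(0, σ²ₐ G)`, `G = ZZ'`, `Z = (M − 2p)/√Σ2p(1−p)`, and
   `e ~ N(0, σ²ₑ diag(w_std))`. REML via one eigendecomposition of `G`
   shared across all traits; narrow-sense heritability
   `h² = σ²ₐ/(σ²ₐ+σ²ₑ)` tested with a boundary-corrected LRT (½·χ²₁ tail).
3. **Backsolve GWAS** — marker effects recovered from the breeding values,
   `ĝ = Z'G⁻â`, with `T = ĝ/√Var(ĝ)` and `p = 2[1 − Φ(|T|)]`; provably
   identical to fitting each marker as a fixed effect in the same mixed
   model (EMMA-style), and per-gene FDR by Benjamini–Hochberg over all
   markers (merged across a gene's transcripts).
4. **eQTL calling and classification** — intervals spanning the first to last
   significant marker; each eQTL classed as *local* (gene overlaps the
   interval), *distant* (other chromosome), *distant same chromosome*
   (non-significant genotyped markers lie between gene and interval) or
   *plausible local* (no genotyped marker — kept **or** LD-pruned — in the
   gap). Hotspots are single markers associated with strictly more than ten
   genes; a conditional scan on each peak finds secondary peaks.
5. **Co-localization** — pQTL mapped with the same machinery (unit weights,
   FDR ≤ 0.05); for each overlapping eQTL/pQTL pair the pQTL peak SNP is fit
   as a standardized covariate (`y = Xb + Z_SNP·b_SNP + a + e`). A pair is
   significantly co-localized when `b_SNP` passes 0.05/n_tests (Bonferroni)
   *and* conditioning eliminates every significant marker in the eQTL
   interval. Variance tied to the SNP: `σ²_SNP = b²·var(Z_SNP)`, reported as
   `σ²_SNP/(σ²_SNP+σ²ₐ+σ²ₑ)`.
6. **Synthetic F2 generator** — founder lines with a configurable fraction of
   fixed-difference markers, Haldane (Poisson) meiosis through F1 and F2,
   negative-binomial counts with planted local/distant/hotspot architecture,
   and phenotypes sharing causal markers with designated genes, so every
   stage is testable against known truth with no external data.

## Worked example

```bash
cat > demo.toml <<'TOML'
[sim]
n_f2 = 200
n_chrom = 5
markers_per_chrom = 200
n_genes = 300
TOML
eqtlcross run --config demo.toml --out demo_out --seed 11
```

which prints (after per-stage timing logs on stderr):

```
93 eQTL, 2 pQTL, 3 significant co-localizations
```

The simulated study plants 60 local genes, 30 distant genes, one hotspot
marker driving 12 genes and ~200 null genes for 200 F2 animals. The run
recovers 93 eQTL; `hotspots.tsv` flags the planted hotspot (marker `M4_22`,
12 associated genes, plus a tightly linked proxy with 11). `eqtl.tsv` carries
one row per (gene, chromosome) record, e.g.

```
response    chrom  start     peak_pos  n_snps  h2     class
G_local_1   chr1   13930348  15920398  5       0.514  local
G_local_3   chr5   73631840  73631840  1       0.389  distant_same_chr
```

`h2_genes.tsv` holds per-gene σ²ₐ, σ²ₑ, h², the halved-χ² LRT p and its BH
q-value; `coloc.tsv` lists each overlapping eQTL/pQTL pair with `b_SNP`, its
Wald p, the Bonferroni cutoff used, whether conditioning eliminated the eQTL,
and the proportions of expression and phenotypic variance explained by the
peak SNP. For example, the gene sharing its causal marker with phenotype
`P_shared_1` is flagged significant with `b_SNP = 0.36` (p ≈ 1.4e-11) and
27.9% of expression variance attributed to the SNP.

Stage-by-stage commands (`eqtlcross simulate|preprocess|h2|eqtl|classify|pqtl|coloc`)
operate on the plain-text artifacts (dosage/map/count TSVs, BED annotation,
phenotype CSV) written by `simulate`; every table is re-derivable from the
stage inputs.

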