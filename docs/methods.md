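# Methods

## Model

The prediction model is the single-kernel linear mixed model

    y = X b + Z g + e,    g ~ N(0, K σ²_g),    e ~ N(0, I σ²_e),

where K is any relatedness kernel over the individuals: a
haplotype-similarity kernel (annotation-guided or naive), or VanRaden's
SNP kernel G = MM′ / (2 Σ_k p_k(1 − p_k)) with dosages centered by
twice the ALT-allele frequency. X defaults to an intercept column; Z
defaults to the identity (one record per individual) but an
observation-level incidence is supported. All variance components are
non-negative; heritability is reported as σ²_g / (σ²_g + σ²_e).

The kernel is a modelling choice, not an estimate of pedigree
relatedness: similarity kernels are on an arbitrary scale (per-block
diagonals in [1, 2]) and σ²_g absorbs the scale. Optional
standardization divides the averaged kernel by its global maximum;
because the mixed model is scale-equivariant this changes σ̂²_g but not
predictions, and it is exposed as an explicit separate step applied
*after* block averaging.

## Haploblocks

Within a scope (a gene's mapped markers, or a chromosome) blocks grow
greedily from left to right: starting from one SNP, the next SNP joins
the block as long as the number of distinct gamete haplotypes over all
2n gametes stays within `max_alleles` (default 10); the SNP whose
inclusion pushes the count *strictly above* the threshold closes the
block and becomes the first SNP of the next one. A block with exactly
`max_alleles` alleles is allowed. Blocks partition each scope;
single-SNP genes yield single-marker blocks; monomorphic blocks are
retained with a warning (their similarity degenerates to the trivial
1×1 case) since marker QC is upstream of this package.

Gene mapping uses closed 1-based intervals extended by `flank_bp`
(default 5000 bp) on both sides regardless of strand; a SNP inside
several overlapping extended genes enters every such gene's scope,
because genes are treated independently and their block kernels are
averaged — no de-duplication rule is applied.

## Similarity measures

For two haplotype alleles over N SNPs:

* **H1** — proportion of matched loci, h₁ = nₛ/N.
* **H2** — segment-length-weighted: matched positions are grouped into
  maximal runs of consecutive SNPs; a run of nₛₗ SNPs scores nₛₗ², a
  single matching SNP scores 1; h₂ = √(Σₗ nₛₗ² / N²). The
  normalizer N² is the score of a perfect match, and the square root
  keeps the score in [0, 1]. (The compact formula for h₂ is sometimes
  written without the square root, but both defining worked values —
  0.71 = √0.50 and 0.17 ≈ √0.03 — include it, so the square root is
  applied here.)
* **HI** — identity: 1 for identical strings, 0 otherwise.

Individual relatedness for a block is the half-sum of the four
cross-gamete allele similarities; the genome-wide kernel is the
unweighted element-wise mean over blocks (every block counts equally,
whatever its SNP length or gene). Internal arithmetic is full
precision; two-decimal agreement with printed reference matrices is a
test tolerance (±0.005), never a rounding step in the computation.

Similarity kernels carry no positive-semidefiniteness guarantee.
Repair happens only at model-fitting time: eigenvalues above
−10⁻⁶·λ_max are clipped to zero; more negative spectra get the minimal
diagonal jitter (logged). Kernels as written to disk are untouched.

## REML and BLUP

REML is profiled over the ratio δ = σ²_g/σ²_e. Projecting y onto an
orthonormal basis of the complement of col(X) and eigendecomposing the
projected kernel once reduces the restricted likelihood to

    −2 ℓ_R(δ) = (n−p)·log σ̂²_e(δ) + Σ_i log(δ d_i + 1) + const,

with σ̂²_e(δ) in closed form, so the fit is a bounded scalar search in
log δ over [−25, 25] (tolerance 1e-8) plus explicit evaluation of both
boundaries; boundary solutions (σ²_g = 0 or σ²_e ≈ 0) are reported
with a flag. When the projected spectrum is numerically flat (kernel ∝
identity) the genetic and residual components are not separately
identifiable and the fit warns rather than claiming a spurious
optimum. Fixed effects are GLS at the fitted components; predictions
for unobserved individuals are

    ĝ_test = K[test,train] (K[train,train] + λ̂ I)⁻¹ (y − X b̂),
    λ̂ = σ̂²_e/σ̂²_g,

identically zero when σ̂²_g = 0. Phenotype pre-adjustment fits
y = Xb + u + e with u ~ N(0, G σ²_u) and returns y − X b̂.

`KernelGBLUP` exposes this as a scikit-learn-style estimator over a
precomputed kernel (`fit(K, y)`, `predict(K_cross)`, fitted attributes
with trailing underscores), so it composes with sklearn tooling; the
module-level functions are thin wrappers.

## Cross-validation

Predictive ability is assessed by repeated k-fold CV (default 20 × 5).
Per replicate, individuals are randomly partitioned into folds sized as
evenly as possible; per fold the model is refit on the training
individuals and the Pearson correlation between predicted genetic
values and the held-out (pre-adjusted) phenotypes is recorded
per fold, not pooled. The kernel is phenotype-free and computed once on
all individuals, so no information leaks from test phenotypes. The
summary is mean ± SE with SE = sd/√(cells) over all replicate × fold
cells; since the cells are stored, any alternative summary is
recomputable. Folds leaving fewer than 3 training individuals or a
single test individual are errors.

## Synthetic data

The generator emulates the structure the method targets: phased SNPs,
protein-coding genes, and polygenic traits with genic haplotype
architecture. Each gene (and each intergenic segment) carries a founder
pool of distinct haplotypes with a mutational genealogy: a few
ancestral haplotypes (default 3) and founders copied from a random
ancestor with each position flipped with probability 0.15. Gametes walk
the scopes of a chromosome keeping the previous scope's founder index
with probability 1 − r (default r = 0.3), which creates decaying
between-scope linkage disequilibrium.

QTL genes (default half of all genes) assign each founder haplotype a
normal effect *inherited along the genealogy*: the ancestral effect
plus an innovation of standard deviation 0.5·√(mutations). This is the
identity-by-state ≈ identity-by-descent premise of haplotype kernels —
sequence-similar alleles carry correlated effects because they share
descent. With ancestry-free founder pools (iid random strings) sequence
similarity between distinct alleles is informationless by construction
and no sequence-similarity kernel can beat a SNP kernel; the genealogy
is therefore a modelling requirement, not a tuning knob. An additive
SNP-effect mode exists for contrast experiments. Environmental noise is
scaled so var(g)/var(y) matches the target heritability (default 0.5)
in expectation; the realized value is stored in the truth record.

Defaults: 300 individuals, 2 chromosomes × 10 genes, 4–8 SNPs per gene
200 bp apart, 2–5 intergenic SNPs per gap placed outside the 5 kb
flanks, 8 founders per scope. Eight founders keep whole genes within
the default 10-allele block threshold while giving clearly
multi-allelic blocks.

What the generator does **not** emulate: mutation after founding,
within-scope recombination, demography, realistic allele-frequency
spectra, genotyping error or missingness. Passing tests therefore show
the machinery is correct and that the method behaves as designed when
its premise holds — not that annotation-guided kernels will beat GBLUP
on any particular real population (on real data the advantage depends
on recombination landscape and trait architecture).

## Validation suite conditions

The end-to-end suite (`tests/test_acceptance.py`) uses desk-scale
problem sizes chosen as package defaults: the exact worked example
(5 × 10); 200 random scopes (≤ 30 SNPs, ≤ 60 gametes) against a rescan
oracle; 100 random blocks for kernel algebra properties; a 2000-point
restricted-likelihood grid at n = 50 and Henderson-MME solutions at
n = 10; heritability recovery over 50 replicates at n = 200, h² = 0.5;
a null-trait CV check at n = 200 using 10 independent null responses as
the bootstrap unit (cells sharing one response are correlated through
its chance alignment with the kernel, so they are not exchangeable);
and an architecture-matching comparison of the genic H1 kernel against
VanRaden GBLUP over 50 simulated replicates at n = 300 with 4 × 5-fold
CV per replicate, summarized by a one-sided sign test (only the paired
sign per replicate enters, so fewer CV repeats per replicate suffice
than in the full 20 × 5 protocol).

## Numerical choices and limitations

* Allele tables are ordered by first appearance scanning individuals in
  input order, slot 0 before slot 1 — outputs are reproducible
  byte-for-byte.
* The greedy block growth counts alleles incrementally by re-labelling
  gametes per added SNP; results are identical to rescanning from
  scratch (tested) but O(total SNPs · gametes).
* `minimize_scalar(bounded)` can in principle miss a local optimum in a
  multimodal restricted likelihood; both δ boundaries are always
  evaluated, and the grid oracle in the tests guards the single-kernel
  case, which is unimodal in practice.
* Missing or unphased genotypes are hard errors — the similarity
  algebra has no missing-data rule, and imputation belongs upstream.
* Autosomal diploid throughout; no handling of sex chromosomes or
  hemizygosity.
* Multi-kernel models (e.g., genic + residual-SNP) and dominance or
  epistatic components are out of scope.
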