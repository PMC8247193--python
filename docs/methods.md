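# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, module by module in pipeline order.

## Data model and conventions

Genomic coordinates are 1-based inclusive everywhere inside the package;
BED input/output converts at the boundary.  Genotypes are dosages of a
counted allele in {0, 1, 2} with `nan` for missing.  For PLINK binary
filesets the counted allele is A1 of the `.bim`; for `.ped`/`.map` (which
carry no allele column) it is the lexicographically smaller symbol
observed at the marker, and the orientation of a marker at which only one
symbol is ever observed is unrecoverable — such markers are read as
dosage 0.  This ambiguity is inherent to the text format and irrelevant
after QC, which removes monomorphic markers.  Pedigrees are stored
topologically sorted; parents referenced but never listed become
founders.

## Synthetic data generator

The generator emulates the structure of a flock-based sheep breeding
study at desk scale and carries full ground truth.

* **Pedigree**: non-overlapping generations, random pair matings without
  selfing, configurable founders/generations/litter size.  Default
  ~1000 animals (200 founders, 4 generations).
* **Genotypes**: gene dropping.  Founder haplotypes are drawn in
  Hardy–Weinberg proportions at frequencies uniform on
  `founder_maf_range` (default 0.05–0.5, a flat post-QC array spectrum);
  transmitted gametes recombine under the Haldane map at 1 cM/Mb.  An
  unknown parent's gamete is drawn from founder frequencies.  Mendelian
  consistency is exhaustively checkable and tested.
* **Phenotypes**: breeding value = planted-QTL term + infinitesimal
  polygenic term.  QTL effects are multivariate normal across traits with
  the target genetic correlation structure (nearest-PSD projection of the
  pairwise targets), rescaled so the QTL explain `qtl_variance_fraction`
  of σ²ₐ among founders; `qtl_effect_distribution="equal"` gives every
  QTL the same |effect| (random sign), the appropriate architecture for
  detection benchmarks where each planted locus must carry a comparable,
  detectable share.  The polygenic term descends the pedigree as parent
  average plus Mendelian sampling with variance halved per known parent.
  Phenotype = trait mean + flock + birth-year + season effects (each
  level drawn once from N(0, (0.5 σ_p)²), a non-trivial but estimable
  fixed-effect structure) + breeding value + N(0, σ²ₑ) residual.  Trait
  panel defaults (six traits, h² 0.05–0.36, means and phenotypic
  variances, key genetic correlations, 50/8/2 fixed-effect levels,
  17% of phenotyped animals genotyped, female-only records) mirror the
  motivating study design.
* **Expression atlas**: 87 tissues in 13 organ systems, 6 samples per
  tissue (~520 total) spanning three age stages and both sexes.  Gene
  baseline log2-expression ~ N(4, 2), per-sample noise N(0, 1), planted
  tissue-specific genes get +log2(fold change) in their tissue; columns
  are rescaled to TPM.
* What the generator does **not** model: selection and assortative
  mating, overlapping generations, flock–family confounding, dominance
  and epistasis, LD between atlas genes and their genomic positions,
  and RNA-seq count noise (expression is log-normal, not negative
  binomial).  Passing tests therefore demonstrate correctness of the
  estimators under their own model assumptions, not robustness to every
  feature of real data.

Each operation consumes an independent substream
`default_rng([seed, stream_id])`, so stages are individually reproducible.

## Genotype and phenotype QC

Marker screen defaults: call rate ≥ 0.90, MAF ≥ 0.01, HWE exact
P ≥ 1e-6, mapped autosomal position required; individuals need call rate
≥ 0.90.  Removal order — unmapped → sex chromosomes → individual call
rate → SNP call rate → MAF → HWE — with frequencies recomputed after
individual removal; the order is a declared convention and the filter is
idempotent.  The HWE test is the exact conditional test (two-sided, in
log space): all heterozygote counts with the observed parity and allele
counts are enumerated and those no more probable than the observed
configuration are summed; the test suite checks it against a
rational-arithmetic enumeration oracle over all tables with n ≤ 50.
Phenotype outliers beyond 3 SD of the trait mean are set missing in a
single pass (no re-iteration, for reproducibility); the boundary is
strict.  LD is composite (genotypic) r² — the squared Pearson correlation
of dosage vectors with pairwise-complete observations — since genotypes
are unphased.

## Relationship matrices

* `A` by the tabular method with inbreeding, `a(i,i) = 1 + a(s,d)/2`.
* `A⁻¹` sparse by Henderson's rules with inbreeding (Quaas): per-animal
  Mendelian-sampling variance `dᵢ = 0.5 − 0.25(F_s + F_d)` with
  `0.25(1+F_p)` restored per unknown parent.
* `G = Z D Z′ λ`, Z centered by `2pᵢ`, missing dosages mean-imputed to
  `2pᵢ` (zero contribution), monomorphic markers excluded,
  `λ = 1/Σ 2pᵢ(1−pᵢ)`.  Centering is adopted because λ is the VanRaden
  scale.  Note `G` built from sample frequencies is singular by
  construction (the centered columns annihilate the ones vector), which
  is why tuning/blending precedes any inversion.
* Tuning is two-moment: solve `α + β·mean(diag G) = mean(diag A₂₂)` and
  the same for off-diagonal means, then blend
  `G_w = 0.95(α + βG) + 0.05 A₂₂`.  The two-moment version subsumes a
  single diagonal-matching factor (reported as β) while guaranteeing
  compatibility of both moments; 0.95/0.05 blending is standard
  single-step practice for invertibility.
* `H⁻¹ = A⁻¹ + [[0,0],[0, G_w⁻¹ − A₂₂⁻¹]]`.  Dense symmetric inversions
  use Cholesky with a one-shot 1e-8 diagonal jitter fallback (logged);
  a matrix that still fails raises.  The identity `H₂₂ = G_w` (genotyped
  block of the inverse of `H⁻¹`) serves as the non-circular test oracle.

## REML

The restricted likelihood is computed to the constant convention
`−½[log|V| + log|X′V⁻¹X| + y′Py]`.  Fitting reparametrizes exactly in the
eigenbasis of `K` (the relationship submatrix of recorded animals): after
one symmetric eigendecomposition, every iteration — likelihood, gradient,
average-information matrix — costs O(n·p²), which keeps 50-replicate
recovery studies at n = 1000–2000 within minutes on one CPU.  Updates are
average-information steps with step-halving and a PSD projection
(eigenvalue clipping) whenever a raw step leaves the parameter space, and
an EM-flavoured gradient step `θ²·∇/n` when the AI matrix is singular;
convergence is relative parameter change < tol (default 1e-8).  Standard
errors come from the inverse of the final AI matrix; h² and r_g standard
errors by the delta method.  The grid-search oracle (dense likelihood on
a 20×20 grid around the optimum) is part of the test suite.

Design choices: traits are fitted pairwise bivariate rather than jointly
(all reported quantities are pairwise; numerically robust at desk scale);
bivariate fits use animals with complete records for the pair; fixed
effects are treatment-coded with the first factor absorbing the
intercept; a rank-deficient design raises rather than silently dropping
columns.  When handed a relationship *inverse* (e.g. sparse `H⁻¹`), the
full matrix is inverted before subsetting, because the submatrix of an
inverse is not the inverse of the submatrix.

## WssGWAS

The mixed-model equations are assembled densely (fixed-effect block,
incidence to all pedigree animals, `σ²ₑ/σ²ₐ · H⁻¹` on the additive block)
and solved directly; the solution's residual ratio is recorded and tested
(< 1e-8).  The reweighting loop runs exactly in the order: D = I → G →
H⁻¹ → GEBV → `û = λDZ′G_w⁻¹â_g` → `dᵢ = ûᵢ²·2pᵢ(1−pᵢ)` → trace
normalization → rebuild G.  `n_reweight` counts weight updates; the
default 1 reflects the standard choice that more iterations concentrate
weight on large effects at the cost of GEBV accuracy.  Backsolving uses
the blended `G_w` (the matrix actually inside H); on unblended full-rank
toys the identity `Zû = â_g` holds to 1e-6 and is tested.

Windows slide by 1 SNP, 20 SNPs wide, never spanning chromosomes;
chromosomes shorter than the window yield one truncated, flagged window
excluded from ranking.  Window variance is the empirical 1/(n−1) variance
of window genomic values across genotyped individuals (the denominator
convention is declared here; genotyped individuals only, since genomic
values of ungenotyped animals would require imputation).  QTL calling
walks windows in rank order: a window overlapping or book-ended adjacent
to an existing region merges into it, otherwise it seeds a new region
while fewer than k exist, and scanning stops at the first window that can
do neither.  With step-1 sliding windows the best windows are always
neighbours of one peak, so distinct merged regions — not raw windows —
are the meaningful unit of reporting; k = 10 regions by default.  Genes
for downstream set analyses come from the top 1% of ranked windows
(ceiling), by any bp overlap.

## Tissue specificity

`y = z-scaled log2(TPM + 0.25)` per gene across samples.  The 0.25
pseudo-count is used consistently on the log scale; "scaled" is read as
per-gene standardization (the alternative — per-sample — would measure
relative composition, not gene-wise specificity).  For a target tissue,
samples of the same organ system other than the target are excluded and
the remaining samples are coded +1 (target) / −1 (outside the system);
organ-system targets use all samples.  Age stage and sex enter as
drop-first dummy factors; collinear covariate columns are dropped with a
warning (the contrast itself is never dropped).  `t = β/SE` with
residual df n − p and an SE floor of 1e-12 (perfect separation yields a
large finite t).  The top 10% of genes by t (ties by gene id) form the
tissue's gene set.  Fits are vectorized across genes: one shared design
per target, solved once.

## Enrichment

`T_sum = Σ b²` over markers within gene-start − 20 kb to gene-end + 20 kb
(clamped at 1; strand ignored) of any set gene, with `b` the final
WssGWAS SNP effects.  The null rotates the genome-ordered effect vector
by a uniform offset in {1, …, n−1} — one circle over the whole genome,
which preserves the set's marker count exactly and all but one adjacency
of the LD structure; per-chromosome circles would preserve slightly more
adjacency but allow offset collisions on short chromosomes.  The
one-tailed p uses the add-one convention `(1 + #{T ≥ T_obs})/(1 + n_perm)`
(never zero, so BH is well-defined); ties count against rejection.
Default 10,000 permutations; BH-FDR within trait across tissues.
Calibration (fraction of null p < 0.05 ≈ 0.05) and agreement with an
exhaustive-rotation oracle are tested.

## Pipeline

Stage seeds derive from the global seed by a labeled SHA-256 hash, so any
stage can be re-run independently; re-running a config reproduces outputs
byte-for-byte.  Defaults are the standard analysis settings (20-SNP
windows, one reweight, top-10 QTL regions, top-1% window genes, top-10%
tissue genes, 20-kb extension, 10,000 permutations).

## Problem sizes in the automated checks

The test suite and `scripts/acceptance.py` run the recovery studies at
desk scale, chosen as the smallest sizes at which the targeted quantities
are statistically identifiable: h² recovery with 50 (tests) or 10
(script) replicates of ~1000 records; genetic-correlation recovery with
20/8 replicates of ~2000 records; QTL detection with 2000 genotyped
animals × 5000 SNPs and 5 equal-share planted QTL (10/3 seeds);
enrichment with 1500–2000 markers and 1000 permutations; the atlas at
2000 genes.  The zero-heritability boundary check uses 200 full-sib
families of five, a design informative enough that a null additive signal
is estimated near the boundary.

## Known limitations

* Pairwise bivariate REML does not pool information across all six
  traits as a joint fit would; estimates of σ²ₐ for the same trait can
  differ slightly between pairs.
* The AI-REML SEs are asymptotic; at boundary estimates (σ²ₐ → 0) they
  are unreliable, as usual.
* The eigendecomposition approach assumes one record per animal and a
  shared relationship structure across traits; repeated records would
  need a different solver.
* Window variance percentages from overlapping windows do not sum to
  100%; they are a ranking device.
* The cyclical permutation preserves LD only approximately at the
  rotation seam and across chromosome joins.
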