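# Methods

This note documents the models implemented in `spectragwas`, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical choices that matter.

## Reflectance calibration

Relative reflectance is computed from four radiance scans per sample —
white reference, black reference, leaf on white, and (optionally) leaf on
black:

    R(λ) = panel(λ) · (S_leaf_on_white(λ) − S_black(λ)) / (S_white(λ) − S_black(λ))

Subtracting the black reference removes additive instrument offsets, and
normalizing by the white reference (with its known panel reflectance,
default 1.0) removes the illumination and sensitivity spectrum. When the
leaf-on-black scan is available, a dual-background variant substitutes it
for the bare black reference, correcting for light transmitted through the
leaf and returned by the background; which variant better matches a given
instrument protocol is not decidable in general, so both are provided and
the single-background ratio is the default. Negative values (possible in
noisy bands) are preserved for diagnostics unless clamping is requested.

Spectra are restricted to 400–2500 nm — the 350–399 nm region of field
spectroradiometers has too little signal — and linearly interpolated onto
the integer 1-nm grid (2101 bands). Linear interpolation is adequate
because instrument output is already near 1-nm resolution; the bias of
higher-order schemes would be far below the noise floor.

## Outlier screening

Spectra are embedded in their top principal components (default 10; raw
2101-dimensional Euclidean distances are noise-dominated) and scored with
the local outlier factor (k = 20 neighbors). LOF ≈ 1 marks inliers. The
flagging threshold (default 1.5) is a conventional LOF operating point; it
is an explicit, logged parameter rather than an estimated quantity, and the
report retains k, the embedding dimension and the threshold for audit.
Band-wise masking and automatic threshold selection are out of scope.

## Environmental adjustment

For each wavelength the model

    Y ~ LN + REP + BA + LN:REP + LN:BA + DT + CT + DT:CT + MO

is fitted by OLS with treatment contrasts (first level reference). LN is
the measurement technique (leaves per clip), REP the replicate set, BA the
spatial patch, DT/CT day and time of day (both treated as factors — their
level counts are small and no functional form is assumed), MO maternal
origin. The compact operator forms expand to LN:REP + LN:BA (technique ×
spatial) and DT + CT + DT:CT (temporal main effects and interaction).
Aliased columns are dropped greedily in term order via an orthonormal-basis
rank test (tolerance 1e-8 relative), with a warning naming the dropped
columns. Missing factor cells are an error, never imputed.

Residuals are the adjusted phenotypes; because the model contains an
intercept they have exactly zero mean per wavelength. Variance is
partitioned by sequential (Type I) sums of squares in the declared order
(technique → spatial → temporal → maternal), which is what a stacked
per-wavelength variance profile requires; the percentages plus the residual
share sum to 100 by construction. Genotype-by-environment interactions are
deliberately not modeled: removing them would also remove genotype main
effects, which downstream association scans need.

Patch effects default to a categorical BA factor. Alternatively, replicated
phytometer plants (a single tester genotype interspersed through the field)
yield continuous patch covariates: per patch and broad wavelength block
(VIS 400–700, NIR 701–1300, SWIR 1301–2500 nm), the mean phytometer
deviation from the grand phytometer mean. Patches without a phytometer get
covariate 0 with a warning. Scalar phenotypes (the spectral indices) are
adjusted with the same design via `adjust_scalar`.

## Spectral indices

Six band-ratio indices are evaluated at exact integer bands of the gridded
spectrum (no averaging window, since spectra are 1-nm gridded upstream):
NDWI = (R865−R1614)/(R865+R1614), CIre = R783/R704 − 1,
CCI = (R560−R664)/(R560+R664), ARDSI_Cab = (R750−R730)/(R770+R720),
ARDSI_Cw = (R1360−R1080)/(R1560+R1240),
ARDSI_Cm = (R2200−R1640)/(R2240+R1720). A zero denominator yields NaN
rather than an error. All six are invariant to rescaling the spectrum, and
the normalized-difference forms are antisymmetric under swapping their
numerator bands — both properties are tested.

## HSC-PA: hierarchical spectral clustering with parallel analysis

The dimension-reduction method at the package's core recursively
bipartitions the wavelength set of the adjusted spectra:

1. **Stop rule (parallel analysis).** For the current band subset, the
   eigenvalues of the band correlation matrix are compared rank by rank
   with the 95th percentile of eigenvalues from 100 null datasets, each
   obtained by independently permuting every band across samples.
   `n_retained` counts leading observed eigenvalues exceeding their null
   percentile, stopping at the first failure, floored at 1 so every branch
   ends in a usable phenotype. The permutation null is distribution-free;
   a Gaussian null would also be defensible but assumes marginal normality
   the residual spectra need not have. The percentile criterion (rather
   than the mean-eigenvalue rule) is the stricter, more common choice.
2. **Split rule (spectral graph bipartition).** If `n_retained > 1`, band
   similarity is the squared Pearson correlation across samples — squared
   so that anti-correlated bands, which a PC treats identically up to
   loading sign, group together (absolute correlation is available by
   config). The bands are split by the sign of the Fiedler vector (second
   eigenvector of the symmetric normalized Laplacian I − D^(−1/2) S
   D^(−1/2)); zero entries join the smaller side, and degenerate
   similarity falls back to a band-index median split with a warning. On
   small instances this sign split coincides with the exhaustive minimum
   normalized cut, which the tests verify on ≤ 12 bands.
3. **Recursion.** Breadth-first from the full grid, with node ids in
   breadth-first order (root = 1, level 1). Guard rails: segments with
   fewer than `min_bands = 5` bands or at `max_depth = 8` become terminals
   regardless (8 matches the deepest level such trees reach in practice on
   full-range leaf spectra). Terminals partition the grid; the terminal
   count always equals the internal-node count plus one.

Each terminal yields one phenotype: the PC1 score of its (train-centered)
submatrix, loading sign chosen so the loading sum is positive, standardized
to mean 0 and variance 1 on the fitting data. Segments need not be
contiguous — bands co-driven across a gap end up together. Segment
numbering is structural (breadth-first) and carries no meaning across
datasets; correspondence between runs is by band set.

Eigenvalues are computed from singular values of the standardized n × p
submatrix (O(min(n,p)² · max(n,p)) per null replicate), which makes the
permutation null affordable even at the 2101-band root.

## Association scans

Genotypes are additive alternate-allele dosages (0/1/2) from a VCF
(multi-allelic records skipped and counted; missing genotypes mean-imputed
per SNP), SNP ids `chr{N}_{pos}`. Kinship defaults to VanRaden's centered
cross-product scaled by 2Σp(1−p); the `zhang` option rescales the same
matrix to unit mean diagonal, a documented approximation of the
GAPIT-style normalization whose exact constant is not published. A 1e-6
diagonal jitter keeps K numerically PSD.

The GLM scan is per-SNP OLS (intercept + optional covariates + dosage)
with a two-sided t test on the dosage coefficient, computed by
residualizing dosage and phenotype against the base design — this equals
the closed-form univariate regression exactly, which the tests assert. The
MLM adds a polygenic random effect with covariance σ²_g K: the variance
ratio is estimated by REML on the null model through the
eigendecomposition of K (grid search over log δ ∈ [−8, 8] refined by
bounded scalar minimization), and under P3D (the default) reused for every
SNP, each tested by GLS with a Wald t test; exact per-SNP re-estimation is
a flag. With K = I the MLM collapses to the GLM identically. Monomorphic
SNPs carry NaN results with no p value. Dominance is not modeled, and no
genomic control is applied — the inflation factor λ_GC is reported only.
FarmCPU- and BLINK-style multi-locus models are not reimplemented; the
result schema carries a model tag so externally computed results can be
pooled into the top-k comparison.

## Multiple testing and candidate genes

PhenoSpD: per SNP j, the LD score is Σ r² with all SNPs within 1 Mb on the
same chromosome (self included, so the floor is 1; the window size is a
convention, not estimated). For each trait pair the product of association
z scores is regressed on the LD score; the intercept estimates the
phenotypic correlation (under a null of no shared genetics the product has
mean ρ, while polygenic signal loads on the slope). The matrix is
symmetrized, clamped to [−1, 1] and projected to the nearest PSD
correlation matrix before eigendecomposition. The effective number of
independent tests is the participation ratio

    Meff = (Σ λ_i)² / Σ λ_i²,

which equals M for uncorrelated traits and 1 for perfectly correlated
ones; Nyholt's and Li–Ji's estimators are selectable alternatives. The
genome-wide threshold is α/Meff (α = 0.05), applied to Benjamini–Hochberg
adjusted p values (per phenotype, across all SNPs): an association is
significant iff its BH-adjusted p falls below α/Meff. A direct
phenotype-correlation mode exists for when phenotype values (not just
summary statistics) are at hand.

The top-k comparison ranks unique SNPs by their minimum p across
phenotypes (and models, when several result sets are pooled — pooling is a
runtime decision, not hard-coded), takes the k-th min-p (k = 50) as a
dynamic exploratory threshold, and reports every association at or below
it; ties at rank k break by (chromosome, position) for determinism, with
tied SNPs retained. These exploratory reports are kept separate from
Meff-based significance calls in all outputs.

Candidate genes are GFF3 `gene` features whose [start, end] intersects
[pos − 100 kb, pos + 100 kb], both boundaries inclusive, positions 1-based
as in VCF/GFF3; distance is 0 inside the gene, else bp to the nearest
edge. An optional id whitelist (e.g. genes with leaf expression evidence)
filters the table.

## The simulator

The generator emulates a MAGIC field study so that every stage has ground
truth:

* **Founders**: 26 inbred lines (the canonical MAGIC panel size), binary
  alleles drawn i.i.d. per SNP with the per-SNP founder allele frequency
  constrained to `maf_range` by construction (an integer carrier count is
  drawn uniformly among the feasible counts). No founder phylogeny is
  modeled: MAGIC populations are bred precisely to erase structure, so
  unstructured founders are the right null.
* **RILs**: each line starts as a hybrid of two independent founder
  mosaics (a stand-in for the funnel cross) and is selfed
  `selfing_generations = 6` times with Poisson(`crossovers_per_chrom`)
  breakpoints per meiosis. Per-locus heterozygosity halves each selfing
  generation (tested against the closed form 0.5 · 2^(−g) at maf 0.5).
  Inflated heterozygosity readings caused by low-coverage imputation in
  real datasets are an artifact and are not emulated.
* **Spectra**: an analytic leaf-like base template (logistic red-edge rise,
  Gaussian chlorophyll wells at 450/680 nm, a green bump, water wells at
  1450/1940 nm, SWIR decline) — not a radiative-transfer model, since only
  correlation structure matters for testing — plus causal-SNP dosage
  effects on declared bands, per-sample latent factors with
  pigment/structure/water/dry-matter/overall-brightness profiles,
  Gaussian level effects for each design factor and interaction (flat
  across wavelengths), and wavelength-dependent noise (elevated at the
  blue end and in the strong SWIR water bands). A configurable fraction of
  samples (default 25%, one per 2 × 2 planting square) are phytometers:
  genetic and latent effects zeroed, environment shared.
* **Truth record**: planted causal SNPs, realized per-term environmental
  variance fractions (relative to the summed component variances, so they
  lie in [0, 1] and sum below 1), the noise profile, phytometer flags and
  the seed.

What the simulator does **not** emulate: realistic LD decay (founder
alleles are i.i.d. across SNPs), pleiotropy beyond band effects, spectral
detector-boundary artifacts, genotype-by-environment interaction, and the
physics linking leaf chemistry to reflectance. Passing tests therefore
demonstrate statistical correctness of the machinery under the stated
generative model, not biological validity on real leaves.

All simulation functions are byte-deterministic given their seed
(per-node RNG streams in HSC-PA derive from (seed, node id)).

## Problem sizes used in the tests and acceptance run

The test suite and `scripts/acceptance.py` run desk-scale versions of the
study: 150–400 lines, 60–10,000 SNPs, and HSC-PA either on synthetic block
designs (rank recovery, split-oracle and four-block checks at 100–150
samples, SNR 10) or on a 5-nm subsample (421 bands) of the full-range
spectra — subsampling intervals up to 10 nm are standard practice for
field spectra and do not change the correlation structure the method
exploits. The acceptance run simulates 250 RILs × 3000 SNPs over 4
chromosomes with one major-effect locus on 1400–1500 nm (+0.015
reflectance per allele, ≈ 0.6 phenotype SD on its segment — the scale of
effect a field study of a few hundred plants can detect), 25% phytometers,
small environmental terms and a dominant brightness latent factor, which
together put the residual (genetic + unmodeled) variance share in the
70–90% range typical of well-controlled field spectroscopy.

## Known limitations

* The Fiedler-sign split approximates the minimum normalized cut; it is
  exact on well-separated band blocks (and verified against exhaustive
  search there) but can differ on graphs without block structure.
* P3D reuses null-model variance components for every SNP; for loci of
  very large effect the exact per-SNP REML flag is more accurate and
  proportionally slower.
* The LD-score regression intercept is an unbiased correlation estimate
  only when sample overlap between trait GWAS is complete (as here, where
  all traits are measured on the same plants).
* The `zhang` kinship rescaling approximates, not reproduces, GAPIT's
  normalization.
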