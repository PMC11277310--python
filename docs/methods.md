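# Methods

This note records the models, estimators, numerical choices and known
limitations behind `petalgwas`, in the order the pipeline runs.

## Petal scenes and the vision pipeline

A petal photograph is modelled as a bright ellipse (the petal) and a white
disk of known physical diameter (1 cm) on a dark background. The synthetic
renderer draws both shapes with 4× supersampled anti-aliasing and optional
Gaussian pixel noise, and returns the analytic truth alongside the image:
area = πab, eccentricity = √(1−(b/a)²), axis lengths 2a and 2b, perimeter by
Ramanujan's second approximation, circularity = 4π·area/perimeter². The
renderer refuses scenes where the petal leaves the frame or touches the disk,
and its intensity levels are validated to leave enough contrast for edge
detection (≥ 0.15 between background, petal and disk).

Segmentation follows the classic gradient recipe:

1. **Gradient mask** — Sobel gradient magnitude thresholded at
   `threshold_scale ×` an automatic base threshold. The base is Otsu's
   threshold on the gradient magnitude; `threshold_scale` (default 1.0) is
   the fine-tuning knob. A constant image yields an empty mask with a
   warning.
2. **Directional dilation** — two perpendicular line structuring elements of
   `line_length` px (default 3, odd required) applied sequentially, closing
   gaps in the edge chain.
3. **Hole filling** — interior background components not connected to the
   border are set true.
4. **Smoothing** — `smooth_iterations` (default 2) erosions with the same two
   line elements. The edge mask straddles the true contour and the dilation
   pushes the filled outline outward by roughly `line_length − 1` px; two
   erosions cancel that bias. On rendered ellipses with semi-axes 80–300 px
   this brings the measured area within ~0.5 % of the analytic truth, versus
   a systematic +2–3 % with a single erosion. Setting it to 0 reproduces the
   raw fill.

The reference disk is found independently of the petal: the brightest class
of a 3-class Otsu split is binarized and candidate regions are filtered by
circularity ≥ 0.9 and size bounds. Exactly one candidate must survive; zero
or several is an error that lists what was found, rather than a guess.
`pixels_per_cm` is the region's area-equivalent diameter over the expected
physical diameter. Calibration accuracy on rendered 120-px disks is within
±1 px/cm; the residual ~0.5 px underestimate comes from the threshold sitting
slightly inside the anti-aliased rim.

Measurements come from `skimage.measure.regionprops` on the largest non-disk
component: area as pixel count, perimeter by the Crofton (line-intercept)
estimator — chosen so a rasterized circle's circularity approaches 1, which a
raw boundary-pixel count does not — and lengths/eccentricity from the
ellipse-equivalent second central moments. Seven descriptors are computed per
petal; by default six (length, width, area, perimeter, eccentricity,
circularity) feed downstream tables, `ratio` being derivable as width/length.
`ratio` is defined as minor/major (≤ 1). Whether petal "length" should be the
ellipse-equivalent major axis or a bounding-box extent is genuinely open for
real petals; the ellipse-equivalent axis is used because it is
rotation-invariant and moment-based. Wing and keel petals occur twice per
flower; replicate frames are averaged per sample.

Limitations: single-petal scenes only, no illumination or lens-distortion
correction, and eccentricity of near-circular regions is intrinsically noisy
(d ecc/d(b/a) → ∞ as b/a → 1), so rasterization alone can move a perfect
circle's eccentricity to ~0.03.

## Synthetic genotypes and phenotypes

Genotypes follow a Balding–Nichols hierarchy. Ancestral allele frequencies
are uniform on `maf_range` (default 0.05–0.5). Each of three subpopulations
(default sizes 123:90:96, matching a cultivar/landrace/wild resource panel)
perturbs them by Beta(p(1−F)/F, (1−p)(1−F)/F) with per-subpopulation F
(defaults 0.05/0.10/0.15, spanning the differentiation a domestication series
shows). Within a subpopulation, samples come in families of `family_size`
(default 5) whose frequencies take a second, nested Balding–Nichols
perturbation at `family_divergence` (default 0.15). The family layer matters
twice over: resource panels of a selfing crop really do contain close
relatives, and a kinship matrix with only three structure eigenvalues above a
flat bulk leaves the genetic variance nearly unidentifiable — REML then sits
on the boundary and the scan loses its structure control. With family blocks
the kinship spectrum is dispersed and σ²_g is estimable at n ≈ 300.
Genotypes are Hardy–Weinberg draws given the family frequency; missingness is
applied uniformly at `missing_rate`. Markers are unlinked (no LD decay is
modelled), so locus-resolution claims from these simulations are about
single-marker recovery, not fine-mapping.

Phenotypes follow `y = Σ β_j g̃_j + √h²·u + c·f + σ·e` with standardized
causal dosages g̃, a polygenic term `u = K^{1/2} z` (so the mixed model is
correctly specified under the null — this is what makes the type-I-error
tests meaningful), a latent "organ size" factor `f` shared by all petal and
seed traits with loading `c`, and iid noise. Two traits sharing only the
factor have expected correlation `c²/(h² + c² + σ²)`;
`loading_for_target_r()` inverts that. Defaults (h² = 0.3, c = 0.8,
σ = 0.65) put the petal–seed correlation near 0.47, inside the 0.40–0.54
band reported for real petal/seed trait pairs. The factor is a statistical
stand-in for coordinated organ growth, not a mechanistic claim.

Expression counts are negative-binomial (dispersion 0.1 by default) for two
conditions × two timepoints × three replicates, with designated genes
carrying multiplicative fold changes; exon lengths are drawn per gene so
FPKM's length normalization is exercised.

## Mixed-linear-model scan

Kinship is VanRaden's genomic relationship matrix
`K = WW′ / (2 Σ p_j(1−p_j))` with W the dosage matrix centred at twice the
allele frequency and missing calls mean-imputed per marker.

The null model `y = Xβ + u + e`, `u ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)` is
fitted by REML profiled over δ = σ²_e/σ²_g. The restricted likelihood uses
the spectral decomposition of `S(K + I)S` (S the residual-forming matrix of
X), reducing each evaluation to O(n); δ is maximized on a 61-point log grid
spanning 1e−5..1e5 and refined by bounded Brent iteration (`xatol` 1e−8). A
maximum on the upper grid edge is treated as σ²_g = 0. The implementation
reproduces a dense-matrix REML evaluation to ~7 significant digits.

The scan holds (σ²_g, σ²_e) fixed at the null estimates for every marker —
the "population parameters previously determined" strategy — so after one
eigendecomposition of K each marker test is a weighted least squares in the
rotated basis: t-statistic on the marker effect with n − p − 1 degrees of
freedom and the residual variance re-estimated per marker. With K = I and
σ²_g = 0 the rotation is orthonormal and every per-marker p equals the OLS
p exactly (observed agreement ~1e−15). Monomorphic markers get β = 0, p = 1
with a warning count. Optionally the leading k kinship eigenvectors join X as
structure covariates (default 0 — the polygenic term already carries the
simulated structure).

The Bonferroni threshold is `α / n_independent` (default α = 0.01) with
`−log10` reported; a `one_over_n` mode gives the alternative `−log10(1/n)`
reading of the same recipe, since both phrasings circulate. `n_independent`
is a user input; a greedy LD-pruning helper (r² > 0.2 within a 50-marker
window) can estimate it. Peaks are distance-clumped: the lowest-p significant
marker absorbs significant markers within 500 kb (configurable) and the
process repeats — a deliberate, documented choice where practice varies
between distance, LD and visual clumping. Candidate windows are
`[pos − 250 kb, pos + 250 kb]` clipped to the chromosome, with 1-based
inclusive gene-span overlap.

## Population-genetic estimators

Per-site nucleotide diversity uses the unbiased estimator
`π_site = (2N/(2N−1))·2p̂(1−p̂)` with 2N the observed allele count; a site
needs ≥ 4 called alleles (configurable) or it is dropped. Windowed π divides
the per-site sum by the window width in bp (20 kb default, non-overlapping).
F_ST is Weir & Cockerham's (1984) variance-component estimator; windows
aggregate as the ratio of summed a-components over summed (a+b+c) — the
weighted form standard in window scans — with a per-window mean of ratios as
an option, and advance by 2 kb. Sites where any population has fewer than two
genotyped samples are excluded. Tajima's D uses the 1989 constants with
`π_total` the un-normalized window sum of per-site heterozygosity and the
sequence count n taken as the window-median observed allele count — a
pragmatic rule for missing data, which the classical formula does not
address. Per-sample heterozygosity reports observed het calls, the
HWE-expected sum of 2p(1−p) over that sample's called sites, and
F = 1 − obs/exp.

Two-locus LD on unphased diploids estimates the four haplotype frequencies by
EM: every genotype pair except the double heterozygote contributes known
haplotypes; the double-het mass is split between cis and trans in proportion
to the current `f00·f11 / f01·f10` odds, iterated to 1e−8 (≤ 1000
iterations). r² = D²/(p₁q₁p₂q₂) and D′ = |D|/D_max follow. Monomorphic
variants are skipped. Haplotype-block construction and phasing are out of
scope.

## Haplotype screen

A "haplotype" here is the ordered string of 0/1/2 genotype codes over the
SNPs inside a gene span (or inside its CDS intervals) — a genotype-level
convention appropriate to a highly homozygous selfing crop; phased inference
is out of scope. Samples with any missing call in the region are excluded
from grouping by default (a `code` policy keeps them with '.' symbols).
Dominant haplotypes must exceed 5 % of the panel strictly — a group at
exactly 5 % is dropped. Every dominant pair with ≥ 3 phenotyped members per
side is tested (Welch's t by default; Wilcoxon rank-sum as an option, both
reported in the long-form output) and a gene is "significant" when any pair
has p < 0.05 on raw p-values; Holm adjustment within a gene segment is
available and recommended when screening many genes, since the
any-pair-rejects verdict is a maximum over correlated tests and its
family-wise rate exceeds the per-test α as the number of dominant haplotypes
grows. CDS verdicts use only CDS-interval SNPs, which is why a gene can be
significant over its full span but untestable or negative over its CDS.

## Interaction statistic and network

For each marker pair a 3×3 contingency table of genotype codes is built over
pairwise-complete samples. The marginal-comparison statistic is

    T = ((R−1)/R) · Σ_{i=1..R} (n_i − m_i)² / (n_i + m_i − 2A_ii),  R = 3.

This is implemented exactly as written. It resembles, but is not identical
to, the classical Stuart–Maxwell marginal-homogeneity chi-square (which
carries no (R−1)/R prefactor); because its null distribution under this
scaling is not established, T is reported as a raw statistic without a
p-value. Terms with a zero denominator force n_i = m_i and are skipped, with
the skip count recorded; a table where all three terms are skipped yields
NaN. T is zero iff all defined row/column margins agree, and is invariant to
transposition and to simultaneous relabeling of both axes.

Network edges default to genotype r² (squared Pearson correlation of the
0/1/2 codes) at threshold ≥ 0.95, with a T-based mode available; both
measures appear in every edge record so either reading can be applied.
Components come from union–find over the passing edges (via networkx);
isolated markers are reported as singleton components, which inflates
component counts relative to an edges-only convention and is documented as
such.

## Phenotype statistics

Pearson correlations use pairwise-complete observations (not listwise) with
two-sided t-based p-values and the */**/*** star convention at
0.05/0.01/0.001; a zero-variance trait raises instead of propagating NaN.
Canonical correlation analysis centres both blocks, QR-whitens them and takes
the SVD of `Q_x′Q_y`; correlations are clipped to [0, 1] and returned
non-increasing with the weight vectors. A rank-deficient block raises an
error naming the candidate collinear columns; no significance test is
attached (only the leading correlation is of interest downstream). Mean-split
concordance dichotomizes each trait at its own mean with "large" meaning
strictly greater; a value exactly at the mean counts as small by default
(`tie_rule="large"` flips it — the convention is arbitrary and documented).
All four cells (LL, LS, SL, SS) are reported rather than a selected pair.
FPKM is `counts × 10⁹ / (total × length)` with guards for zero library size
and non-positive exon length.

## Problem sizes and determinism

Every simulator is a pure function of its configuration and seed (NumPy
`default_rng`). The test-suite and acceptance-script problem sizes — 20
rendered scenes, 300 × 2000 panels for the OLS limit, 5000 markers for null
calibration, 10 seeded replicates for causal-SNP recovery, 400/100 replicates
for haplotype calibration/power — were chosen so each property is measured
with adequate Monte-Carlo precision while the whole pipeline remains a
desk-scale computation. Passing them demonstrates internal correctness and
calibration on data satisfying the generators' assumptions (unlinked markers,
Gaussian traits, clean single-petal scenes); it does not certify behaviour
under LD, trait non-normality, segmentation artefacts, or ascertained marker
panels.
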