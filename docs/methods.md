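# Methods

This note records the models, numerical choices and limitations behind
`thermopheno`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## The measurement model

Canopy temperature is treated as a genotype-level quantitative trait
observed through imaging. For tree of genotype *i*, treatment *t*
(WW = well-watered, mDr = moderate drought), block *b*:

    T_c(i, t, b) = μ_t + g_i + (g×t)_it + block_bt + ε

with independent normal effects: genotype g_i ~ N(0, σ²_G), interaction
(g×t)_it ~ N(0, σ²_G×T), block-within-plot block_bt ~ N(0, σ²_block),
residual ε ~ N(0, σ²_ε). The same decomposition is both the generative
model of the synthetic module and the estimation model of the REML
analysis, so parameter-recovery tests close the loop exactly.

## Synthetic trial generator

The generator emulates the study conditions of a two-plot poplar
short-rotation-coppice drought trial:

| parameter | default | unit | rationale |
|---|---|---|---|
| n_genotypes | 503 | – | analysed cohort size |
| n_blocks | 4 | – | randomized complete blocks per plot |
| mortality_rate | 0.127 | – | observed field mortality |
| row / within-row spacing | 2.5 / 1.0 | m | planting grid |
| pixel_size_m | 0.06 | m | thermal ground sample distance |
| μ_WW / μ_mDr | 19.55 / 21.60 | °C | population mean T_c per treatment |
| σ_G | 1.2 | °C | reproduces the observed genotype-mean range (≈16.6–23.3 °C) |
| σ_G×T | 0.3 | °C | weak rank-changing interaction |
| σ_block | 0.2 | °C | modest within-plot environmental structure |
| σ_ε | 0.9 | °C | genotype-mean SEs up to ≈3 at r ≈ 3.5 imply residual SD of order 1 |
| crown radius | 0.45 ± 0.05 | m | crowns clear the 1-m spacing; buffer (0.40 m) stays inside |
| soil temperature | 40 ± 4, truncated > 28 | °C | sun-exposed bare soil, hotter than any canopy |
| weed temperature | 12 ± 1, truncated < 14 | °C | ground vegetation cooler than the canopy band |
| weed_fraction | 0.05 | – | sparse weed patches (0.3 m disks) |
| sensor_noise_sd | 0.05 | °C | camera thermal sensitivity (<0.05 °C at 30 °C) |
| g_s model | −80·(T_c−T_a) − 170, SD 60 | mmol m⁻² s⁻¹ | rounded from the OLS fit to the parental reference table (slope −81.7, intercept −172) |
| T_a | 28.75 | °C | air temperature at flight time |

Choices the trial description leaves open, fixed once here:

* **Overlapping crowns** take the temperature of the nearest tree center
  (deterministic; overlap is rare at 1-m spacing with 0.45-m crowns).
* **Dead trees** render as bare background, which exercises the
  empty-buffer path in extraction.
* **Weed placement** is random disk patches covering `weed_fraction` of
  the background; only the weed temperature band is constrained.
* **Border rows** (`border_rows`, default 0): optional non-genotyped
  guard rings around each plot, rendered like trees (treatment mean plus
  residual, no genotype effect) and excluded from every statistic — they
  exist to exercise realistic plot edges, mirroring the guard rows of
  field trials.
* **Within-crown heterogeneity** is not modelled beyond sensor noise;
  leaf-to-leaf temperature variance would require an energy-balance leaf
  model, which is out of scope. Consequently, recovery tests demonstrate
  correctness of the *extraction and statistics*, not robustness to
  biological within-crown structure.
* **Truncation** of soil above and weed below the canopy bands makes
  segmentation well-posed by construction. Passing the mask-quality tests
  (≥99% crown coverage, ≤1% background leakage) therefore validates the
  algorithms under separable conditions; on real mosaics the bands can
  overlap the background distributions and the same guarantees do not
  follow.
* **RNG discipline**: every product draws from a named sub-stream of the
  config seed (`layout`, `effects`, `render_WW`, `render_mDr`, `gs`), so
  individual stages are reproducible in isolation and whole bundles are
  byte-identical under a fixed seed.

## Segmentation

**Multilevel Otsu.** The histogram (default 256 equal-width bins over the
valid-pixel range; the bin count mirrors the camera's discretization
convention) is partitioned into K classes (default 9) by dynamic
programming over cumulative zeroth/first moments, O(K·B²), maximizing
between-class variance. Ties break toward the lexicographically smallest
threshold set. Thresholds between non-adjacent occupied bins are placed
at the midpoint of the empty gap. The separability criterion
η ∈ [0, 1] is reported. Quantization levels — not raw pixels — are then
classified against the treatment's canopy band by their pixel-mean
temperature (inclusive bounds; the conservative reading of a stated
range). A `mode="pixel"` flag retains raw in-band pixels instead, for
the alternative reading of band-based retention.

**Region merging.** Regions start as single valid pixels on the
4-connected graph (4-connectivity keeps perimeter accounting exact).
The fusion cost follows the published multiresolution segmentation
criterion — the commercial implementation is closed, only its three
parameter values (scale 10, shape 0.1, compactness 0.5) are adopted:
colour heterogeneity h_color = n·σ, shape heterogeneity
n·(w_cmpct·l/√n + (1−w_cmpct)·l/b) with l the region perimeter and b its
bounding-box perimeter; a merge of A and B costs the increase of the
area-weighted sum, f = (1−w_shape)·Δh_color + w_shape·Δh_shape, and is
allowed while f < scale². Merging proceeds by local mutual best fitting
(pairs that are each other's cheapest neighbour merge simultaneously),
which is order-independent and deterministic; remaining ties resolve
toward the smallest region label. The resulting segments are classified
by mean temperature exactly like Otsu levels, so the two routes share
the classify-by-mean contract.

Soil- and weed-classified pixels are set to nodata before extraction
("null temperature"), so they can never leak into a buffer mean.

## Extraction

A pixel belongs to a tree's buffer iff its *center* lies within the
radius (default 0.40 m — conservative for 1-m within-row spacing); the
rule is grid-resolution independent and makes buffer means invariant to
common translations of raster and coordinates. Trees whose buffer
contains no retained pixel are flagged empty and excluded from genotype
summaries — a nulled canopy is a missing measurement, not 0 °C.
Genotypic summaries (mean, SD/√n, n) use alive trees with defined T_c;
the replicate filter keeps genotypes with ≥ 3 replicates in both
treatments (`min_reps` configurable).

## Statistics

* **ANOVA**: sequential (Type I) sums of squares in the order Genotype,
  Treatment, G × T — the default of the statistical environment this
  analysis tradition comes from; the design is near-balanced, making the
  SS-type choice second-order. Exposed via `ss_type`.
* **Box-Cox**: λ maximizes the profile log-likelihood of the additive
  genotype + treatment model over the grid [−2, 2] in 0.01 steps
  (deterministic; standard range). Applied when Bartlett's test rejects
  at 0.05 (`boxcox="auto"`), or forced/disabled by flag, since the
  original gating is not documented.
* **Block adjustment**: observed − (block mean − plot grand mean),
  separately per plot, applied only when a one-way block ANOVA within
  the plot is significant at α = 0.05. The additive location shift is
  the minimal method achieving equal block means; the cited source for
  the original adjustment gives no formula.
* **REML**: treatment fixed, genotype and G × T random. The restricted
  log-likelihood is maximized directly (L-BFGS-B with the analytic
  gradient, then Newton polish on the gradient) rather than by EM-type
  updates: EM's linear convergence near a zero variance component cannot
  reliably deliver the 1e-6 agreement with the balanced-design
  expected-mean-squares estimator that the oracle tests demand, while
  the gradient-based optimum matches it to ~1e-14. The likelihood is
  evaluated blockwise per genotype and batched over identical replicate
  structures, so a 500-genotype fit takes well under a second. Estimates
  are clipped at zero; asymptotic SEs come from the numerical Hessian.
* **Heritability**: H²_within uses r = average replicates per genotype
  within a treatment; H²_combined uses n = number of treatments and
  r = average replicates per genotype over the experiment. Both r's are
  computed from the data (arithmetic mean by default, harmonic as an
  option).
* **Shape statistics**: population-moment skewness and *excess* kurtosis
  without small-sample bias correction, so a normal sample scores
  (0, 0).
* **Cross-method agreement**: Spearman ρ with average ranks on ties and
  Student's t, paired on genotype by default (the same genotypes are
  measured by both segmentation routes); unpaired available.
* **g_s validation**: OLS of conductance on (T_c − T_a). The fit reports
  both the two-sided p-value and the one-sided p-value for the
  directional hypothesis of an inverse relation; on the parental
  reference means (n = 8) the two-sided test sits just above 0.05
  (p ≈ 0.054) while the directional test is significant (p ≈ 0.027).

## Stress Susceptibility Index

SSI uses genotypic mean temperatures on the °C scale (the index is
ratio-based, so Kelvin would change the numbers; °C follows the field
convention). The denominator uses the ratio of population mean
temperatures over the retained (≥3-replicate) cohort; a flag switches to
the population mean of per-genotype ratios. Tolerance requires quadrant
Q4 (T_c,mDr > T_c,WW and T_c,mDr below the population drought mean) and
*strictly* 0 < SSI < 1. Points exactly on a biplot axis go to the
lower-numbered adjacent quadrant — deterministic and measure-zero.

## Problem sizes and tolerances

The acceptance computations use the full study scale (503 genotypes,
two ~1.5-Mpixel mosaics, both segmentation routes; about a minute
end-to-end). Statistical calibration uses 500 null replicates with
binomial 99% acceptance bands; parameter-recovery checks accept within
3 estimated standard errors. For the recovered population mean, the
standard error combines the genotype-mean spread (shrinks with the
number of genotypes) with the shared block effects, whose plot-mean
contribution σ_block/√n_blocks does not shrink — with 4 blocks this term
dominates.

## Known limitations

* The generator produces binary crown/background pixels; real thermal
  mosaics have mixed boundary pixels, sharpening the importance of the
  segmentation step beyond what synthetic tests measure.
* Orthorectification, lens undistortion and mosaicking are upstream of
  this package (performed by flight-processing software); only the
  GCP-based affine georeferencing is modelled.
* REML assumes Gaussian responses (a linear mixed model); the analysis
  applies Box-Cox first rather than changing the response family.
* The region-merge segmenter is single-band and unweighted by texture;
  it targets thermal mosaics, not general imagery.
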