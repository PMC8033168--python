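# Methods

This note records the models, parameter choices and numerical conventions
behind `ramanxome`, and what the synthetic benchmark does and does not show
about real data.

## The measurement model the generator emulates

A hyperspectral map is a grid of per-pixel spectra on a shared wavenumber
axis (default 600–1800 cm⁻¹ at 1 cm⁻¹, 1201 channels — the fingerprint
region containing every band the analysis uses, and comfortably longer than
the 99-channel smoothing frame). Each pixel is

```
spectrum(pixel) = component(compartment, condition) + baseline + N(0, σ²)
```

* **Compartment components** are sums of Gaussian peaks
  (center, FWHM, amplitude). The nucleus carries nucleic-acid bands at 752,
  786 (amplitude 1.0 — the intensity unit of the whole simulation), 1095 and
  1578 cm⁻¹ plus protein bands; the cytoplasm is protein/lipid-dominated
  (1004, 1304, 1450, 1660 cm⁻¹ with a weak 786); the background is a broad
  coverslip/PBS-like hump, so background subtraction is non-trivial.
* **Condition effects** are multiplicative on named peaks. Activation (D4)
  scales the nucleus 786 cm⁻¹ amplitude by **0.8** — the planted marker the
  classifier must find — and mildly remodels cytoplasmic bands
  (1660 × 1.12, 1304 × 1.10), so cytoplasm and whole-cell spectra also carry
  condition signal, as they do in activated B cells. Without the latter, a
  cytoplasm-based cross-modal model would regress on pure noise, which is
  not what the emulated study observed.
* **Geometry**: one disk cell per map with a disk (optionally kidney-shaped:
  disk minus an offset notch disk) nucleus, sampled per map. Full-size maps
  are 75×75 px at 0.2 μm (15×15 μm), cell radius U(4.4, 5.2) μm, nucleus
  radius 0.60–0.68 of the cell radius — B-cell-like large nuclei. A compact
  preset (31×31 px, cell radius ≈ 2.7 μm) keeps many-map cohorts cheap;
  pixel size is unchanged so the 3 μm QC rule stays meaningful.
* **Per-map nuisance variation**: baseline scale ~ N(1, 0.03) (focus /
  coverslip drift), a lognormal (sd 0.05) global amplitude factor on all
  cell peaks, and an extra lognormal (sd 0.05) factor on the nucleus
  786 cm⁻¹ band (biological spread of the marker). These create the
  within-condition spread visible in real peak-ratio distributions, and they
  also make the pooled noiseless cohort contain far more than k distinct
  spectra, so k = 10 clustering of piecewise-constant maps is well posed.
* **Noise**: additive iid Gaussian, default σ = 0.1, i.e. SNR ≈ 10 on the
  unit-amplitude 786 cm⁻¹ band. Gaussian (rather than Poisson) noise is the
  simplest model supporting SNR sweeps; shot-noise scaling is a
  non-goal.

The transcriptome is a count matrix (default 2000 transcripts × 6 samples,
3 per condition) with NB(mean m, var m + φm²) marginals, common dispersion
φ = 0.05 (a typical cell-line value; φ = 0 degenerates to rounded means).
Baseline abundances are log2-uniform in [3, 9]. A designated informative
subset (default 30) has log2-scale means affine in the sample's Raman
PC-score vector: target PC columns are standardised across samples, the
main (activation-axis) coefficient has magnitude U(0.8, 1.8) with random
sign — condition fold-changes of roughly 3–16×, the scale of real
activation programs, whose hallmark immunoglobulin switch genes move even
more — and the remaining axes get small N(0, 0.1) coefficients.
Non-informative transcripts are condition-constant by construction. Each
sample's counts come from an RNG substream keyed by the sample id, so
reordering samples permutes columns and nothing else.

## Segmentation

Common k-means pools every pixel of every map (float32) and runs Lloyd's
algorithm with Euclidean distance, k-means++ starts (best of n_init = 10 by
final within-cluster sum of squares), centroids accumulated in float64.
Distances are computed as ‖c‖² − 2x·c with the per-pixel norms added only
for inertia, so one iteration is a single BLAS product. The k-means++
seeding runs on a deterministic 20 000-pixel subsample (falling back to the
full data if the subsample has fewer than k distinct spectra); Lloyd always
runs on every pixel. A restart stops when labels are stable or the squared
centroid shift falls below 1e-4 of the total pixel variance, after which
labels and centroids are re-synchronised so each centroid is exactly the
mean of its members; the inertia sequence is asserted non-increasing at
every iteration. Empty clusters are re-seeded on the point farthest from
its centroid. Ties in the pixel assignment go to the lowest cluster index.
`k` larger than the number of distinct spectra is an error.

Cluster naming uses two centroid marker scores:

* **cell vs background**: spectral roughness — mean |centroid − its own
  Savitzky–Golay smooth (order 2, frame ≤ 99)|. Cell centroids are peaky,
  the coverslip/PBS background is smooth, and because centroids average
  thousands of pixels the scores differ by orders of magnitude; the split is
  the largest gap in log10 of the sorted scores. A raw intensity total would
  confuse a bright smooth background with a dim peaky cell, which is why
  roughness is the default; an absolute threshold remains available (and can
  declare *everything* background, which is an error).
* **nucleus vs cytoplasm** among cell clusters: mean centroid intensity in
  the nucleic-acid band 786 ± 4 cm⁻¹, split at the largest (linear) gap.
  A fixed "top-N clusters" split is available but not default: how many
  clusters k-means spends on each compartment varies with noise and cohort,
  and a fixed count misassigns whole clusters when it guesses wrong. A
  single cell cluster is named cytoplasm and left to QC. Manual overrides
  (`cluster → compartment`) take precedence over both scores.

Per-map compartment spectra are plain arithmetic means over member pixels;
the whole-cell spectrum is the mean over the union of nucleus and cytoplasm
pixels (pixel-count weighting), not the average of the two compartment
means. QC discards maps with no nucleus or no cytoplasm pixels, or with a
nucleus equivalent-circle diameter 2s·√(A_px/π) strictly below 3 μm
(at-threshold is retained; the equivalent-circle reading of "nucleus size"
is a choice — a largest-connected-component diameter would be an
alternative, and pixel counts are reported so either can be recomputed).

Background subtraction is exactly three steps: (1) subtract from each of
nucleus, cytoplasm, whole-cell **and** background its mean intensity over
the offset band 1780–1840 cm⁻¹ intersected with the axis (21 channels on
the default axis, which ends at 1800 cm⁻¹); (2) Savitzky–Golay-smooth the
background (order 2, frame 99, polynomial fits on truncated windows at the
edges, so spectra keep their length and any degree-≤2 background is
reproduced exactly in the interior); (3) subtract the smoothed background
from the three cell spectra.

## Spectral discrimination

Peak intensity is the windowed mean over center ± 4 cm⁻¹ on corrected
spectra (no local baseline; the window covers the peak FWHM without
touching the 752/786 neighbour). The 752/786 ratio uses intensity(752) /
intensity(786); cells with a non-positive denominator are excluded with a
warning. All two-group tests are Welch (unequal-variance) two-sided
t-tests; the degenerate all-identical case is reported as statistic 0,
p = 1.

PCA is centered SVD with components ordered by explained variance and a
deterministic sign convention (each loading's largest-magnitude element is
positive). The per-PC t-tests cover the first 9 components by default with
no multiplicity correction (a Holm option exists). LDA is the Fisher
discriminant on the selected PC scores (default: all 9), scaled so the
pooled within-class variance of the LD scores is 1, oriented so D4 projects
high, thresholded at the midpoint of the projected class means (equal
priors; the cohorts are near-balanced). A singular within-class scatter —
e.g. scores confined to a low-dimensional subspace — gets a ridge of
1e-8·tr(S_w)/d with a warning. The wavenumber-space loading spectrum is the
coefficient-weighted sum of the selected PC loadings.

Leave-one-out fits the PCA once on all cells and refits only the LDA in
each fold (standard chemometrics practice; the holdout's spectrum then
contributes to the subspace but not to the discriminant). `strict=True`
refits the PCA inside every fold and projects the held-out spectrum onto
the fold's loadings; on the synthetic cohorts the two schemes agree.
Sensitivity and specificity take D4 as positive.

## Cross-modal PLS

Pseudo-replicates are a uniform random balanced partition of each
condition's cells (sizes within one cell, e.g. 58 → 20/19/19), averaged in
PC-score space; the partition seed is recorded. Pseudo-replicates are
paired to count-matrix samples by index order within each condition —
replicates are exchangeable, so the pairing is a bookkeeping convention.

Count features are log2(1 + count), centered per transcript with
**training-sample** means only; no unit-variance scaling, so abundant
transcripts keep their magnitude structure (autoscaling is a flag).
PLS2 uses NIPALS with deflation of both X and Y: the inner power iteration
runs to a 1e-12 relative change (it converges to the dominant eigenvector
of XᵀYYᵀX), components stop early if the X residual is exhausted (the
noiseless low-rank case), and β = W(PᵀW)⁻¹Qᵀ. The default A = 2 latent
components reflects the design's capacity: six samples leave at most four
centered degrees of freedom in a leave-one-out fold, and the planted
structure is two-dimensional (activation axis + one secondary axis).
Responses are the PC scores of the retained components (default 9).

Leave-one-sample-out refits the PLS without sample i (every fold must keep
both conditions) and predicts R̂ᵢ = Tᵢ·β₋ᵢ; predictions are converted to LD
scores with the single-cell discriminant and called D0/D4 against its
threshold. Exact held-out prediction is only possible when the held-out
sample lies in the training row space, which is why the planted cell scores
live in an exact rank-2 subspace: group means inherit the rank, and with
A ≥ 2 the noiseless leave-one-out residual is at numerical zero. VIP is
computed on the full six-sample model (a per-fold VIP with median rank
aggregation is a flag); its mean square over transcripts is identically 1,
which every fitted model asserts in tests.

## Problem sizes and determinism

The test suite and acceptance script run everything at sizes a laptop core
handles in minutes, chosen once as the package's benchmark conditions:
segmentation recovery on 10 + 10 full-size (75×75) maps, noiseless and at
default noise; a 50 + 50-cell compact-grid cohort for the classifier,
VIP-recovery and compartment-robustness analyses (k-means restarts reduced
to 3 there — the clustering landscape of the structured cohort is benign,
and restart count is an algorithmic knob, not a data condition); 20-run
brute-force k-means oracles at n ≤ 8; 10-seed sweeps for stochastic
recovery medians; 50 fuzzed cohorts for I/O round trips. Every random
choice flows from explicit integer seeds through `numpy.random.Generator`;
map rendering, cohort simulation and clustering are bit-reproducible given
the seed, and the HTML report rebuilds byte-identically (fixed SVG hash
salt, timestamps confined to the run manifest).

## What passing on synthetic data does and does not show

The generator reproduces the statistical *structure* the analysis assumes —
shared axes, compartment-pure piecewise spectra plus smooth background,
a multiplicative condition effect on a known band, counts with an exact
low-rank linear link — so passing tests demonstrate the pipeline recovers
planted truth under those assumptions, with honest noise and nuisance
variation. It deliberately does not model confocal optics: no point-spread
function, no out-of-focus cytoplasm bleeding into nucleus pixels (a real
effect the discussion of nucleus-spectrum purity in the source study turns
on), no cosmic-ray spikes, no wavenumber miscalibration between sessions,
no library-size or GC composition effects in the counts, and no
non-linear transcriptome–phenotype coupling. Real-data sensitivity and
specificity will be worse than the synthetic figures; the synthetic
acceptance surface checks correctness of the machinery, not instrument
performance.

## Known limitations

* The largest-gap cluster-naming rule assumes both cell and background
  pixels exist in the cohort; single-compartment cohorts need an explicit
  threshold or override.
* With only six samples, the count-route group calls are themselves noisy
  (leave-one-out shrinks predictions toward the wrong class mean when the
  link is weak); the exactness guarantees hold in the noiseless low-rank
  limit only.
* Welch tests on 3 + 3 samples have t-distributed, not Gaussian, coverage;
  generator no-leak checks are therefore calibrated against a null
  simulation rather than the nominal 95% / 2σ rule.
* The NB dispersion is common across transcripts; no mean–dispersion trend.
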