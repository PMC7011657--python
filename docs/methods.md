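# Methods

`statefish` decomposes single-cell gene-expression variability into a
cell-state (extrinsic) component, shared between genes, and an
allele-specific (intrinsic) component, uncorrelated between genes. This
note records the models, the synthetic-data assumptions, the numerical
choices, and what passing tests do and do not establish.

## The conditioning model

For each gene *g* with counts *y<sub>g</sub>* over cells, an ordinary
least-squares fit on the measured cell-state features *X* (intercept always
included) produces residuals *r<sub>g</sub>*; the **conditioned** expression
is *r<sub>g</sub>* + mean(*y<sub>g</sub>*) ("mean add-back"), so the
conditioned distribution keeps the raw mean and can go negative. Negative
values are preserved: clipping would bias the dispersion statistics
downward. Counts enter untransformed; a `transform` hook exists on
`VarianceDecomposition` but is off by default, and no technical-noise
correction is applied — the Poisson limit of 1 is therefore only a
theoretical floor.

Dispersion is summarized per gene by the Fano factor Var/mean (1 for a
Poisson process) and CV² = Var/mean², both with the unbiased (n−1) variance
estimator and the raw mean in the denominator. Covariance structure is
summarized by the gene–gene Pearson matrix and by the fraction of variance
captured by the first two principal components of the per-gene z-scored
matrix (**correlation PCA**; a config switch disables the z-scoring). The
no-structure baseline is the same statistic after independently permuting
each gene across cells.

**Stages.** Conditioning runs over a nested plan — raw → volume → volume +
cell-cycle scores → all 13 observed features — and a final stage appends
`n_hidden = 2` "hidden" features: the leading principal components of the
z-scored conditioned matrix of the previous stage, capturing shared
cell-state variation the measured features missed. The hidden factors are
extracted from residuals and then re-conditioned jointly with the observed
features; they are not jointly re-estimated.

A note on monotonicity: the PC1+2 fraction need **not** decrease at every
nested stage. Conditioning on mostly idiosyncratic features shrinks
per-gene variance faster than shared variance, so the explained *fraction*
can rise at an intermediate stage (we observe this adding the cycle
scores). It does decrease from raw to the full model to the hidden stage,
and that is what the tests assert.

**Category attribution** splits each gene's full-model R² by incremental
R² with categories added in a fixed order (volume → cell cycle →
differentiation → calcium); shares telescope exactly to the full-model R².
An averaged-over-orderings (Shapley-style) variant is available behind the
`average_orders` flag since fixed-order attribution favors early
categories when features correlate.

**Permutation significance.** On volume-adjusted counts, each calcium
feature's slope in the full calcium OLS model is compared with a null
distribution of slopes from refits in which only that feature's column is
permuted (default 1600 resamples; fewer than 100 is refused because the
null SD becomes unstable). Reported per (gene, feature): z-score against
the null, a two-sided empirical p on |slope| floored at 1/n_resamples, and
Bonferroni adjustment over all gene × feature tests. For speed, one
permutation per resample is shared across genes (a single multi-gene
refit); the marginal null law per test is unchanged. P-values are
two-sided; sidedness in the original description is ambiguous.

## Barcode geometry and decoding

Barcodes are constant-weight-4 binary words of length 24 (8 hybridizations
× 3 colors; bit = 3·(hyb−1)+color, 0-based) with pairwise Hamming distance
≥ 4, built by greedy search over all weight-4 words (lexicographic pass
first, then seeded shuffles, best code kept). Greedy attains the known
optimum 140 at 16 bits but only ~385 at 24 bits; requests beyond the
achieved capacity raise an error carrying the achieved size rather than
promising a fixed capacity.

After L2 normalization every ON bit of a weight-4 barcode is exactly 0.5;
the closest pair of normalized barcodes has dot product 0.5, i.e. angular
separation 60°. The decoding threshold is the chord subtending half that
separation, 2·sin(15°) = 0.5176. An ideal 1-bit dropout (three equal ON
bits) sits exactly on this boundary, so assignment is **inclusive** (with
1e-5 slack for float32 arithmetic) — a strict inequality would silently
disable the code's single-dropout correction. Ties between equidistant
barcodes go to the lowest codebook index.

Preprocessing per bit: non-overlapping groups of three raw optical
sections are max-projected into pseudo-z slices (a trailing partial group
is dropped); high-pass = image − Gaussian(σ 2.2 px), clipped at 0;
optional Richardson–Lucy deconvolution (20 iterations; the PSF is a
Gaussian of σ 1.2 px — the iteration count is canonical, the PSF width is a
configuration choice); Gaussian blur σ 0.9 px; division by the image's
95th-percentile intensity. That percentile presumes a noise floor in most
pixels; on noise-free synthetic images (mostly exact zeros) it is taken
over the positive pixels instead, and an all-dark bit is left unscaled
with a warning. Either way the decoding is invariant to global per-bit
intensity scaling.

Calls are per-pseudo-z-slice 2-D connected components (8-connectivity) of
same-barcode pixels, with intensity-weighted centroids, filtered on pixel
count (default min 2) and mean ON-bit intensity (default off) — the
filters exist in the original description without stated values, and are
applied identically to genes and blanks.

**Error rates.** Sensitivity: each gene call's centroid bit vector is
compared against its full codeword and the four 1-bit-dropout variants;
f_full is the fraction closest to the full codeword, p = f_full^(1/4), and
sensitivity = p⁴ + 4(1−p)p³ (detect all four bits, or exactly three).
With calls as the denominator f_full is biased upward, because spots that
drop two or more bits are never called: at p = 0.908 the call-conditional
fraction is p⁴/(p⁴+4p³(1−p)) ≈ 0.71, not p⁴ = 0.68. Simulations with
known truth can pass `n_true_spots` to use the true denominator; the
real-data path keeps the call denominator and inherits the bias. The
false-positive rate is (blank calls / blank barcodes) / cells — expected
spurious calls per gene per cell.

**Registration.** Bead candidates are peaks of the normalized
cross-correlation against a 3-D Gaussian template, localized to subpixel
precision by cubic upsampling (factor 5) plus a parabolic fit (~0.02 px on
clean synthetic beads). All candidate pair displacements within the
maximum shift are DBSCAN-clustered; the largest cluster's mean
displacement is the least-squares translation. Fields with RMS residuals
over 0.5 px laterally or 1.2 µm axially are rejected.

**Cell volume.** Calls are binned per cell into 1 µm³ voxels, smoothed
with a Gaussian (default σ 10 voxels), and the volume is the count of
voxels at ≥ 0.5 RNA. Calls outside every mask stay unassigned (logged,
not fatal).

## Calcium featurization

GCaMP is divided pointwise by co-expressed mCherry (non-positive mCherry
samples are an error naming the index). The ratio trajectory is split by
a 4-level `bior4.4` discrete wavelet transform: low band = approximation +
two coarsest detail levels, high band = two finest levels (the two sum
back to the input to machine precision); the denoised band soft-thresholds
detail coefficients at the universal threshold. Eight features: peak
counts in the low/high bands (topographic prominence ≥ 0.1 / 0.15, after
the stimulus), the first post-stimulus peak's decay time (to 1/e of
prominence above its own base) and FWHM (width at half prominence), the
post-stimulus trapezoidal AUC of each band (low band above its
pre-stimulus median; high band as |·|), and the maximum of the denoised
band with its time. Cells without a post-stimulus low-band peak get the
sentinel duration + 1 s in time-valued fields plus a `ca_no_peak` flag —
a QC outcome, not an error; the regression receives it as-is.

One deliberate deviation: the first peak is *selected* in the low band,
but its decay/FWHM are *measured* on the denoised band. At a 2–3 s
sampling interval the stimulus transient carries most of its energy at
scales the coarse band suppresses, and low-band widths carry essentially
no information about the true peak geometry (rank correlation with
generator truth ≈ 0, vs ≈ 0.8 for FWHM on the denoised band). All
features except the maximum are invariant to adding a constant baseline
(to reconstruction precision, ~1e-10); the maximum shifts by exactly the
constant.

## The synthetic-data generator

The generator emulates the study conditions — ~150 genes in ~5000 cells
whose log-rates are linear in 13 observable state features — with every
distribution a stand-in (the source data's marginals are not public
knowledge), so feature values must not be read as estimates of real data:

- volume ~ LogNormal(log 2000, 0.35) µm³; cycle phase multinomial
  (0.6, 0.2, 0.2) over G1/S/G2M with S and G2M scores = phase mean ±
  N(0, 0.3); two differentiation markers share a latent axis through a
  log link.
- calcium response: a latent 3-vector gates responsiveness (~84%
  responders), sets first-peak amplitude (softplus), FWHM (25–35 s), rise
  width (2–6 s, so decay and FWHM carry independent information), and
  0–2 later oscillatory bumps. Trajectories are rendered as baseline 1.0 +
  Gaussian-rise/exponential-decay peak + bumps + white noise (default SD
  0.05); the truth features are exact closed forms of these parameters.
  At 5% noise the low band sits near the 0.1 prominence threshold, so
  extracted peak *counts* saturate — a real threshold-sensitivity effect
  that motivates running the decomposition on the observed feature table
  (the default) rather than on re-extracted features.
- rates: rate = exp(b₀ + c·z + w·h) on z-scored features, with baseline
  median ~30 molecules, per-feature coefficient SD 0.05, an extra +0.09
  volume loading on every gene, and a 2-D hidden factor loading (SD 0.15)
  on a seeded ~30% of genes. These scales put the raw median Fano above 2
  while keeping the exponential link in its near-linear regime, which the
  linear conditioning model deliberately mismatches. With substantially
  larger coefficients the *curvature* of the link becomes a coherent
  shared factor of its own (every gene's volume² loading is positive),
  which two hidden PCs cannot absorb — an identifiability limit worth
  knowing about when interpreting hidden-factor stages on real data.
- sampling: Poisson mode draws Poisson(rate); bursting mode draws
  gamma-Poisson with shape rate/b and scale b (negative binomial), mean
  rate and Fano 1 + b per cell — the stationary law of slow two-state
  transcription with geometric bursts of mean size b. Log-rates above a
  cap (default 15) are refused.
- the toy three-TF/two-gene system draws TFs as Poisson(20) and genes as
  Gamma with shape an additive combination of the TFs (gene means exactly
  linear in the TFs, so OLS is the correct conditioning model); the gamma
  scale sets intrinsic variability and the shared-shape fraction the
  correlation. Regimes: intrinsic (scale 10, nearly TF-free shape),
  mixed, extrinsic (scale 0.1, fully TF-driven shape).
- codestacks: each true spot paints a σ 1 px Gaussian at fixed amplitude
  into every ON bit, each bit independently retained with the per-bit
  detection probability; Gaussian background noise is clipped at zero;
  beads paint identically into all bits and into their own channel. No
  photobleaching, aberration, or drift beyond one rigid translation per
  bit. Spot density in tests is kept near 1.5×10⁻³ px⁻² so overlapping
  PSF tails stay rare — at several-fold higher densities tail collisions
  visibly bias the dropout statistics.

Every generator is a pure function of its arguments including the seed;
the pipeline fans a single global seed into per-stage seeds through fixed
`SeedSequence` spawn keys, and a rerun from the saved config is
byte-identical (fixed float formatting in all writers).

## Problem sizes and what the tests show

The headline test uses the study-scale 5000 cells × 150 genes; the
decoder-consistency test uses 10,002 spots over six 1024² fields at
per-bit detection 0.908 (deconvolution off there: the dropout statistic
does not depend on it and the run stays within a couple of minutes); the
permutation calibration uses 200 genes × 8 features × 400 resamples × 20
repetitions. Note that at 400 resamples the empirical p floor (1/400)
already exceeds the Bonferroni cutoff 0.05/1600, so the family-wise error
criterion is met structurally; the z-scores still exercise the full null
machinery.

Passing these tests shows the pipeline's statistics behave correctly under
their own generative assumptions — log-linear rates, Gaussian features,
ideal optics. They do not certify performance on real imaging data, where
feature distributions, optical artifacts, segmentation errors, and the
true link between state and rate all differ; in particular the real-data
magnitudes (median R², raw PC variance, bulk-RNA-seq concordance) depend
on the deposited imaging data and are out of scope here.
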