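# Methods

## Model and assumptions

The analysis treats an en-face OCTA slab as a realisation of a
(second-order) stationary random texture and characterises it entirely
through its normalized spatial autocovariance. This is the central
modelling assumption: everything downstream — the lag curve, the PCA
grading, the pattern bins — is a functional of ρ(d). Anisotropy is
deliberately averaged out by radial pooling; directional texture (e.g.
vessel tracks in the superficial plexus) is visible to the estimator only
through its isotropic average.

### Autocorrelation estimator

* **Unbiased, non-periodic.** Each offset Δ is averaged over its
  N_valid(Δ) = (H−|Δy|)(W−|Δx|) genuinely overlapping pixel pairs.
  Periodic (FFT wrap-around) estimators would correlate opposite borders
  of the retina, which has no physical meaning; the implementation uses a
  zero-padded FFT plus the closed-form overlap counts, and is verified
  against a literal pair-enumeration oracle on small images (≤ 16×16,
  agreement to 1e−9).
* **Global centring.** One mean μ and one variance σ² for the whole
  image (ddof = 0, which is the unique choice making ρ(0,0) = 1 exactly).
  Global centring is also what makes the estimator *exactly* invariant
  under affine intensity maps a·I + b (tested to 1e−10) — important
  because display brightness/contrast is operator-adjustable.
* **Radial binning** by d = round(√(Δx²+Δy²)); bins beyond the maximum
  lag are discarded. Default maximum lag 30 px = 150 μm at 5 μm/px.
* **Features.** Zero crossing = first lag with ρ ≤ 0, reported in whole
  pixels (no sub-bin interpolation); curves positive throughout are
  censored at the maximum lag. Plateau = mean ρ over 100–150 μm
  (bracketing the ~120 μm landmark); both window and lag range are
  configurable.
* **Degenerate inputs.** Constant images are rejected (σ² = 0) rather
  than assigned ρ ≡ 0. The unbiased estimator can slightly exceed |ρ| = 1
  at far lags; retained lags on 512² images keep ≥ 88% pair overlap and
  the suite enforces |ρ| ≤ 1.05.

### PCA grading

PCA is fit on centred, *unscaled* columns (all columns share the ρ unit,
so correlation-matrix PCA would only inflate noisy far lags). The d = 0
column is dropped (constant). Scores come from a full SVD; the
explained-variance ratios sum to 1 and are checked against a covariance
eigendecomposition oracle. The PC1 sign is arbitrary, so the index is
oriented by rule: control mean ≤ case mean when both labels exist,
otherwise non-negative loading sum. Minimum cohort size 3.

### Pattern classification

No published numeric boundaries exist for patterns A–F, so the default
cuts are the pooled 1/6…5/6 quantiles (linear interpolation), persisted
in the run report so any run is reproducible; fixed cuts can be supplied
in config. Coarseness order A, B, E, D, C, F: the caption-level anchors
are A "very rough", B "quite gross", D "quite fine", F "finest"; E is
placed coarser than D (both chronic-associated, D explicitly fine) and C
between D and F (C behaves control-like). Both placements are
configurable and flagged in output. Boundary values fall to the finer
bin — any deterministic rule suffices; this one is stated. Clinical-type
associations (acute/chronic/recurrent) are carried as annotation only;
the package asserts no pattern↔type mapping.

### CFD statistics

The "independent t-test" is implemented in both classical readings —
pooled (default) and Welch — and reports state which was used; both
satisfy the reproduction bounds asserted in the suite. P-values are
two-sided. Summary-path and sample-path tests agree exactly by
construction (the sample path delegates to the summary path). χ² is the
Pearson statistic with marginal-product expectations; zero expected
counts are an error with guidance rather than silently continuity-
corrected. Cohen's κ uses marginal-product chance agreement; two
identical constant raters (p_e = 1) are defined as κ = 1 with the
degeneracy noted. The published summary table is embedded as *input*
data with its own header sample sizes (41/35), which disagree with the
narrative eye counts (40/13); the header is what makes the table
self-contained, so it is used as printed. Four sectors (parafovea,
superior-hemi, temporal, nasal) have printed p-values consistent with
their printed summaries and are used as benchmarks; the others (fovea,
inferior, whole image, thickness, rings A/B/C) are recomputed and
reported but not forced to agree. No multiple-testing correction is
applied (none was in the source analysis).

## Synthetic data: what it emulates and what it does not

Gaussian random fields stand in for vascular texture because the whole
analysis only sees the autocorrelation, which GRFs control exactly:
white noise smoothed with a Gaussian kernel of scale σ has normalized
ACF exp(−d²/4σ²) in closed form. Defaults: 512² px at 5 μm/px, 8-bit
intensity mean 120 / SD 30 (a realistic slab scale, chosen once);
controls σ = 2 px; cases σ = 8 px — which alone puts the 120 μm plateau
at exp(−576/256) ≈ 0.10, inside the 0.05–0.2 band coarse clinical
textures show — plus dark flow-void discs (Poisson centres at
1.5 spots/mm², lognormal radii mean 100 μm / SD 40 μm within the
10–150 μm structure range, 80% attenuation, overlaps multiplying).
Smoothing uses periodic boundaries so the closed form holds without edge
effects; the analysis estimator remains non-periodic. Per-subject seeds
are SeedSequence(master_seed, index), so cohorts are byte-reproducible
and subjects independent. CFD cohorts draw per-sector normals from the
published group parameters, clipped to [0, 100] (clipping probability
< 1% at those parameters).

What the generator does **not** emulate: vessel geometry, OCTA physics
(decorrelation noise, projection and shadow artefacts), segmentation
error, inter-eye correlation, or the six clinical pattern archetypes
(presets are illustrative, not calibrated). Passing tests therefore
demonstrate that the estimator, grading and statistics behave correctly
on textures of known correlation structure — not that the pipeline
reproduces clinical grading on real scans.

## Numerical and design choices

* FFT sizes via `next_fast_len(dim + max_lag)`; overlap counts in closed
  form, no ones-convolution.
* σ-recovery fits exp(−d²/4σ²) by bounded least squares, p0 = 2 px.
* Sextile cuts and IQR use the linear-interpolation quantile definition
  throughout.
* Quality filter keeps rows with signal strength ≥ 6 (configurable);
  rows with *missing* strength pass with a warning, since absence
  usually reflects export loss, not scan quality.
* 16-bit/float image inputs are min–max rescaled to 8-bit on load and
  logged; RGB collapses by BT.601 luminance.
* Centred cropping (default 512) — deterministic and symmetric; the
  border symbols the crop removes sit at image edges.
* Single-run determinism is a contract: given a config, every numeric
  output is reproducible; the config digest, seeds and exclusions are
  recorded in the run report.
* The pipeline accepts any layer (SCP/DCP/ORL/CCL) and tags outputs; it
  does not assert which layers are texture-analysable.

## Problem sizes in the suite

Property checks run at the sizes the claims are stated at: 512² images
for curve-level checks, 20-seed batches for the σ ∈ {2, 4, 8} recovery
ladder (within 15%) and zero-crossing monotonicity, and 20 seeded
10-control + 10-case cohorts for the PC1 zero-overlap separation bound
(≥ 95% of seeds). The brute-force estimator oracle runs on ≤ 16×16
images, where literal pair enumeration is exact and cheap.

## Known limitations

* The grading index is cohort-relative (PCA is refit per cohort); scores
  are not transferable across cohorts without refitting or fixed
  loadings.
* Quantile pattern cuts guarantee balanced bins on the fitting cohort,
  which is a convention, not a clinical calibration.
* Radial pooling discards anisotropy; strongly directional textures with
  identical isotropic averages are indistinguishable.
* The censored zero-crossing value (150 μm) is a reporting convention,
  not an estimate of where the curve would cross.
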