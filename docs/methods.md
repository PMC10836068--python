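# Methods

## Forward model

A pixel's TCSPC histogram records photon arrival times relative to the
last excitation pulse, binned into `n_time_bins` bins of width
`bin_width_ns` (default 256 bins tiling the 12.5 ns period of an 80 MHz
source). The underlying decay is the normalized two-component exponential

    I(t) = a1 exp(−t/τ1) + (1 − a1) exp(−t/τ2),   0 < τ1 < τ2,

with the short component identified with free NADH (physiologically
0.1–0.5 ns) and the long component with bound NADH (1–5 ns).

**Bin integration.** Bin probabilities are exact integrals of the
exponential over each bin (differences of exponentials at the bin edges),
not midpoint samples, so they remain exact at coarse bin widths.

**Incomplete-decay folding.** At 80 MHz the period (12.5 ns) is only
2.5 τ for a 5 ns bound lifetime, so fluorescence excited by earlier
pulses wraps into the current window. Folding is applied in closed form:
summing a single exponential over all wrapped periods is a geometric
series, multiplying that component's per-period mass by
`1/(1 − exp(−T/τ))`. Folding is on by default; as the period grows the
folded model converges to the unfolded one (verified to < 1e−9 sup-norm
at period ≥ 100 τ2). Note that folding changes the *relative weights* of
the two components inside the window (the long component wraps more), not
the within-window shape of either component; consequently the
window-renormalized first-bin probability can decrease even though every
bin's per-pulse arrival mass strictly increases.

**IRF.** The default instrument response is a delta. An optional Gaussian
IRF of standard deviation `irf_sigma_ns` is convolved analytically
bin-by-bin, circularly, matching the folded model's periodic boundary.

**Mean lifetime.** `τm = a1 τ1 + (1 − a1) τ2`; it lies in `[τ1, τ2]` and
is strictly decreasing in `a1` for fixed lifetimes, so more glycolytic
pixels (higher free fraction) have shorter `τm`.

## Synthetic scenes and acquisition

A scene is a list of regions that partition the frame (background is an
explicit region). Each region carries an `a1` mean and standard
deviation, constant lifetimes, and a marker-channel brightness. Per-pixel
`a1` values are drawn from a Gaussian truncated to (0, 1) by rejection,
which keeps region means interpretable while enforcing the fraction
invariant. Lifetimes obey the construction convention τ1 ∈ (0, 1) ns,
τ2 ∈ (0.5, 6] ns, containing the physiological windows.

The simulated cube has expected counts `N_pix · p_j` per bin, where `p_j`
is the folded (and optionally IRF-convolved) model probability and
`N_pix` is the photon budget: `mean_photons_per_pixel` scaled by the
pixel's relative brightness so the brightest region hits the configured
budget. Observed counts are independent Poisson draws. Marker channels
(EGFP/mCherry surrogates) are Poisson images of the region brightness and
are used *only* for masking.

Defaults: 64×64 frames (desk scale; real acquisitions are 512×512 and
are supported), 5,000 photons/pixel. No acquisition-duration or
photon-budget figure is available for the in vivo setting; 5,000 photons
per (unbinned) pixel is a realistic budget for multiphoton NADH FLIM and
is a simulation choice. The generator deliberately omits optics (PSF,
scattering, depth attenuation), motion artifacts, and melanin
absorption, so passing tests demonstrate estimator and pipeline
correctness under Poisson statistics and the stated decay model — not
robustness to those real-data effects.

## Per-pixel estimation

Pixels are first binned 2×2 ("bin of 4"): each pixel's histogram becomes
the sum over its neighborhood, quadrupling counts per decay. The default
semantics is a sliding window anchored at the pixel (edge pixels use the
available sub-window), which preserves frame geometry; a non-overlapping
block mode is provided and conserves the grand photon total exactly.
Note the sliding sum mixes neighboring pixels, so when the true `a1`
field varies spatially the fitted map is a locally averaged version of
the truth — with per-pixel truth scatter of sd 0.05 this imposes an
error floor near 0.03 that photon budget cannot reduce. Estimator-
consistency checks therefore use constant-`a1` scenes, where the error is
photon-limited and shrinks monotonically with the budget.

Tumor pixels are selected by thresholding a marker image (Otsu by
default; fixed-value and quantile rules available); the rule and realized
threshold are recorded as mask provenance.

The fit enforces `a1 + a2 = 1` by parameterizing `a1` alone and profiles
the total amplitude out analytically, leaving a 3-parameter bound-
constrained problem solved by L-BFGS-B with analytic gradients:

- **Poisson MLE (default).** With model means `A·p_j(θ)` and
  `Σ p_j = 1`, the amplitude MLE is the total count, reducing the
  objective to `−Σ y_j log p_j(θ)`. Counts are Poisson, so this is the
  efficient estimator.
- **Weighted least squares.** Neyman weights `1/max(y_j, 1)` for the
  first pass, then two reweighting iterations with weights from the
  fitted model `1/max(Â p̂_j, 1)`. Pure Neyman weighting biases τ2 low by
  a few percent at 1e5 photons; model-based reweighting removes this and
  brings WLS into sub-percent agreement with the MLE asymptotically.

Initialization defaults to τ1 = 0.3 ns and τ2 = 2.5 ns (midpoints of the
free and bound windows) with bounds τ1 ∈ [0.05, 1.0], τ2 ∈ [0.5, 6.0],
a1 ∈ [0, 1]. When a histogram is weakly identifying, the optimizer can
converge with τ1 pinned at its upper bound and τ2 at its lower bound (the
components attempting to swap labels); this corner is detected and the
fit retried from three spread-out starts, keeping the best objective. If
fitted lifetimes come out crossed they are swapped and `a1` relabeled
`1 − a1`. Histograms with fewer than `min_photons = 100` total counts
are flagged unfit (NaN in all maps, False in `fit_ok`) rather than
fitted: below that a two-component decay is practically unidentifiable.
Convergence: relative objective tolerance 1e−9, max 200 iterations.

## Distribution-level statistics

**Value extraction.** Analyses run on finite fitted values at masked
pixels only; unfit pixels are excluded, and an empty selection raises an
explicit condition rather than yielding an empty sample silently.

**Modality.** The pooled `a1` (or `τm`) sample is fitted with k = 1
(closed-form Gaussian MLE) and k = 2 (EM, 10 restarts, k-means++
initialization, tolerance 1e−8, max 500 iterations, seeded). The lower
BIC wins; a BIC advantage below 2 is a tie resolved to k = 1
(parsimony). Mixture fitting uses raw per-pixel values, not binned
counts.

**Group comparisons.** Unpaired two-tailed t-tests operate on per-fish
mean values — the fish, not the pixel, is the unit of inference, avoiding
pseudo-replication (pixel-pooled histograms remain available for
figures). The two-way ANOVA treats group and histogram bin (width 0.01
on a1 ∈ [0, 1], relative frequencies normalized within group) as
crossed factors in an additive linear model and reports the group
effect; this mirrors the histogram-comparison usage. With pooled
histograms there is one observation per group × bin cell, so no
interaction term is estimable; a per-fish table would support one.

## Pipeline reproducibility

One global seed drives everything. Per-stage, per-unit sub-seeds are
derived through keyed `SeedSequence` splitting, so adding a unit never
perturbs the draws of existing units, and rerunning an identical config
reproduces every CSV/JSON output byte for byte. Floats are written with
9 significant digits; lifetimes are in ns, fractions unitless. Each run
directory carries a provenance record (config hash, seed, package
version, per-stage wall time) and a FAILED marker if a stage aborts.

## Validation protocol sizes

All validation runs at desk scale on one CPU: noiseless forward/inverse
consistency over 20 random truths; bimodal-scene recovery on 64×64
frames at 5,000 photons/pixel (seeds 1–5, region-mean `a1` within
±0.02); modality selection on 20 scenes of ground-truth generator draws
(10 unimodal, 10 bimodal at ten-pooled-sd separation); MLE/WLS
equivalence at 1e5 photons over 20 truths (2% relative); and 50
replicates of an 8-fish-per-group brain-like (a1 = 0.75) vs
skeletal-like (a1 = 0.60) study with per-fish sd 0.04 and 8×8 frames per
fish — the per-fish mean from 64 binned decays has a standard error far
below the between-fish sd, so small frames do not influence the
fish-level test.

## Known limitations

- Lifetimes are fitted per pixel; a global shared-lifetime (τ1, τ2)
  fit with per-pixel amplitudes is a common alternative and is not
  implemented.
- No phasor-domain analysis, no ≥3-component or stretched-exponential
  models, no vendor file formats (.ptu/.sdt).
- The two-way ANOVA factor structure is one defensible reading of
  "group × histogram"; pooled-across-fish histograms are the default.
- The synthetic IRF is Gaussian and shift-free; real IRFs are asymmetric
  and can drift.
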