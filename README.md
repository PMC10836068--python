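# flimetab

Metabolic imaging analysis for NADH fluorescence-lifetime microscopy
(FLIM), built around fully synthetic time-correlated single-photon
counting (TCSPC) data so every stage is testable without a microscope.

## The problem

NADH fluoresces with a short lifetime in its free form (~0.1–0.5 ns) and a
long lifetime when protein-bound (~1–5 ns). A TCSPC FLIM acquisition
therefore yields, per pixel, a photon-arrival histogram well described by
a two-component exponential decay

```
I(t) = a1 · exp(−t/τ1) + a2 · exp(−t/τ2),   a1 + a2 = 1,
```

where `a1` is the fractional contribution of free NADH and `a2 = 1 − a1`
that of bound NADH. A larger free fraction `a1` indicates a shift toward
glycolysis; a smaller one indicates oxidative phosphorylation. The
amplitude-weighted mean lifetime `τm = a1·τ1 + a2·τ2` condenses this into
one number per pixel: more glycolytic tissue has higher `a1` and shorter
`τm`. Comparing `a1`/`τm` distributions across tumors and organs — and
asking whether one tumor's `a1` histogram needs one Gaussian or two
(coexisting metabolic subpopulations) — is how metabolic heterogeneity is
quantified in vivo, e.g. in zebrafish melanoma metastases where brain
lesions run more glycolytic than skeletal ones.

`flimetab` implements that pipeline end to end:

- **`flimetab.synth`** — ground-truth metabolic scenes (region-structured
  `a1` fields, unimodal or bimodal) and simulated TCSPC acquisition:
  folded two-component decays at an 80 MHz repetition rate, Poisson
  photon noise, optional Gaussian IRF, and EGFP/mCherry-like marker
  channels for masking.
- **`flimetab.decay_model`** — closed-form decay model shared by the
  simulator and fitter: bin-integrated probabilities, periodic-excitation
  folding (incomplete decay), IRF convolution, mean lifetime.
- **`flimetab.pixelfit`** — 2×2 spatial binning ("bin of 4"), intensity
  thresholding (Otsu / fixed / quantile), and per-pixel constrained
  maximum-likelihood fitting of `(a1, τ1, τ2)` with `a1 + a2 = 1` built
  in; Poisson MLE by default, iteratively reweighted least squares as the
  cross-check objective.
- **`flimetab.stats`** — pooled `a1`/`τm` extraction under the tumor
  mask, single vs bimodal Gaussian model selection by BIC, per-fish
  summaries, unpaired two-tailed t-tests on per-fish means, and two-way
  ANOVA on group × histogram-bin relative frequencies.
- **`flimetab.pipeline` / `flimetab.cli`** — YAML-configured
  simulate → fit → analyze → report runs with full seed-derived
  reproducibility and provenance records.

## Worked example

```python
import numpy as np
from flimetab import AcquisitionConfig, bimodal_scene, build_scene
from flimetab.experiments import fit_scene
from flimetab.stats import select_modality

acq = AcquisitionConfig(frame_shape=(64, 64), mean_photons_per_pixel=5000)
spec = bimodal_scene((64, 64), a1_means=(0.55, 0.75), a1_sd=0.02, seed=1)
truth = build_scene(spec)
fitted = fit_scene(truth, acq, seed=1)

ok = fitted.valid_mask()
for region in spec.regions:
    sel = region.mask & ok
    print(f"{region.label:>15}: fitted mean a1 = {fitted.a1[sel].mean():.3f}, "
          f"mean tau_m = {fitted.tau_m[sel].mean():.3f} ns")
print("modality:", select_modality(fitted.a1[ok], seed=1).k)
```

prints

```
 oxphos-shifted: fitted mean a1 = 0.553, mean tau_m = 1.286 ns
     glycolytic: fitted mean a1 = 0.750, mean tau_m = 0.851 ns
modality: 2
```

The two planted metabolic subpopulations (`a1` = 0.55 and 0.75) are
recovered from 5,000-photon pixels to within a few thousandths; the more
glycolytic region shows the shorter mean lifetime; and the BIC comparison
correctly calls the pooled `a1` distribution bimodal (`k = 2`).

A full multi-fish study runs from a config file:

```sh
flimetab run-all --config examples/demo.yaml --out results/demo
```

which writes per-unit cubes and parameter-map TIFFs, a per-fish summary
CSV, mixture-model and group-test JSON reports, and a histogram/fit
figure.

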