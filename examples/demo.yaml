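# Two-group demo study: brain-like (more glycolytic, higher a1) vs
# skeletal-like lesions, two fish each, 16x16 frames at desk scale.
seed: 7
acquisition:
  frame_shape: [16, 16]
  mean_photons_per_pixel: 5000
fit:
  objective: poisson_mle
  min_photons: 100
  bin_window: 2
threshold:
  rule: otsu
analysis:
  field: a1
units:
  - {unit: brain_1, group: brain, organ: brain, scene: tumor, a1_mean: 0.75, a1_sd: 0.03}
  - {unit: brain_2, group: brain, organ: brain, scene: tumor, a1_mean: 0.72, a1_sd: 0.03}
  - {unit: skel_1, group: skeletal, organ: skeletal, scene: tumor, a1_mean: 0.60, a1_sd: 0.03}
  - {unit: skel_2, group: skeletal, organ: skeletal, scene: tumor, a1_mean: 0.63, a1_sd: 0.03}
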