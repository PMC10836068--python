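"""End-to-end simulation protocols built from the pipeline stages.

These routines bundle the recurring generator -> fitter -> statistics
round trips: bimodal-scene parameter recovery, the 20-scene modality
selection protocol, and the brain-like vs skeletal-like group comparison.
They are used by the validation suite and are convenient entry points for
exploring estimator behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig
from .pixelfit import FitOptions, ROIMask, fit_cube
from .stats import compare_groups, select_modality
from .synth import (ParameterMaps, SceneSpec, bimodal_scene, build_scene,
                    simulate_decay_cube, uniform_scene)


def _full_mask(shape: tuple[int, int]) -> ROIMask:
    return ROIMask(np.ones(shape, dtype=bool), "all-pixels")


def _subseed(seed: int, *key: int) -> int:
    """Stable sub-seed derivation; keyed so streams never collide."""
    state = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(state.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def fit_scene(truth: ParameterMaps, acq: AcquisitionConfig, seed: int,
              opts: FitOptions | None = None) -> ParameterMaps:
    """Simulate one acquisition of a ground-truth scene and fit all pixels."""
    cube = simulate_decay_cube(truth, acq, seed)
    return fit_cube(cube, _full_mask(truth.shape), acq, opts or FitOptions())


def bimodal_recovery(seed: int, shape: tuple[int, int] = (64, 64),
                     photons: float = 5000.0,
                     a1_means: tuple[float, float] = (0.55, 0.75),
                     a1_sd: float = 0.02) -> dict:
    """Recover the two planted region means of a bimodal scene.

    Returns the planted and fitted per-region mean a1 plus their absolute
    errors, using the default Poisson-MLE fit with 2x2 binning.
    """
    acq = AcquisitionConfig(frame_shape=shape,
                            mean_photons_per_pixel=photons)
    spec = bimodal_scene(shape, a1_means=a1_means, a1_sd=a1_sd, seed=seed)
    truth = build_scene(spec)
    fitted = fit_scene(truth, acq, seed=_subseed(seed, 1))
    out = {"planted": list(a1_means), "fitted": [], "abs_error": []}
    for region in spec.regions:
        sel = region.mask & fitted.valid_mask()
        mean_fit = float(fitted.a1[sel].mean())
        out["fitted"].append(mean_fit)
    out["fitted"].sort()
    out["abs_error"] = [abs(f - p) for f, p in
                        zip(out["fitted"], sorted(a1_means))]
    return out


def modality_protocol(seeds: range = range(1, 21),
                      shape: tuple[int, int] = (64, 64),
                      unimodal_mean: float = 0.65, unimodal_sd: float = 0.03,
                      bimodal_means: tuple[float, float] = (0.55, 0.75),
                      bimodal_sd: float = 0.02) -> dict:
    """Modality-selection accuracy over alternating uni/bimodal scenes.

    Half the seeds generate unimodal scenes, half bimodal scenes whose
    component separation (0.20) is ten pooled standard deviations — well
    past the >= 3 sd regime where the two subpopulations are genuinely
    distinct. Selection runs on each scene's a1 values; returns per-scene
    outcomes and overall accuracy.
    """
    seeds = list(seeds)
    records = []
    for i, seed in enumerate(seeds):
        if i < len(seeds) // 2:
            spec = uniform_scene(shape, a1_mean=unimodal_mean,
                                 a1_sd=unimodal_sd, seed=seed)
            true_k = 1
        else:
            spec = bimodal_scene(shape, a1_means=bimodal_means,
                                 a1_sd=bimodal_sd, seed=seed)
            true_k = 2
        truth = build_scene(spec)
        sel = select_modality(truth.a1.ravel(), seed=seed)
        records.append({"seed": seed, "true_k": true_k,
                        "selected_k": sel.k, "delta_bic": sel.delta_bic})
    correct = sum(r["true_k"] == r["selected_k"] for r in records)
    return {"records": records, "n_scenes": len(records),
            "accuracy": correct / len(records)}


@dataclass
class GroupStudyResult:
    """One replicate of the brain-like vs skeletal-like comparison."""

    mean_a1: dict[str, float]
    mean_tau_m: dict[str, float]
    t_statistic: float
    p_value: float
    effect_direction: int
    unit_means_a1: dict[str, list[float]]


def group_comparison_replicate(seed: int, n_units: int = 8,
                               unit_shape: tuple[int, int] = (8, 8),
                               brain_a1: float = 0.75,
                               skeletal_a1: float = 0.60,
                               unit_sd: float = 0.04,
                               pixel_sd: float = 0.02,
                               photons: float = 5000.0) -> GroupStudyResult:
    """Simulate and analyze one brain-like vs skeletal-like study.

    Each group has ``n_units`` fish; a fish's tumor-mean a1 is drawn from
    Normal(group mean, ``unit_sd``), its pixels scatter around that with
    ``pixel_sd``, and the full acquisition + fit pipeline produces the
    per-fish mean fitted a1 and tau_m that feed the unpaired two-tailed
    t-test (fish are the unit of inference). Brain-like tumors are more
    glycolytic: higher a1, hence shorter tau_m.
    """
    acq = AcquisitionConfig(frame_shape=unit_shape,
                            mean_photons_per_pixel=photons)
    rng = np.random.default_rng(_subseed(seed, 0))
    unit_a1: dict[str, list[float]] = {"brain": [], "skeletal": []}
    unit_tau_m: dict[str, list[float]] = {"brain": [], "skeletal": []}
    for g, (group, group_mean) in enumerate(
            [("brain", brain_a1), ("skeletal", skeletal_a1)]):
        for u in range(n_units):
            fish_mean = float(np.clip(rng.normal(group_mean, unit_sd),
                                      0.05, 0.95))
            spec = uniform_scene(unit_shape, a1_mean=fish_mean,
                                 a1_sd=pixel_sd,
                                 seed=_subseed(seed, 1, g, u),
                                 group_label=group)
            truth = build_scene(spec)
            fitted = fit_scene(truth, acq, seed=_subseed(seed, 2, g, u))
            ok = fitted.valid_mask()
            unit_a1[group].append(float(fitted.a1[ok].mean()))
            unit_tau_m[group].append(float(fitted.tau_m[ok].mean()))
    cmp = compare_groups(unit_a1["brain"], unit_a1["skeletal"],
                         test="unpaired_t_two_tailed")
    return GroupStudyResult(
        mean_a1={g: float(np.mean(v)) for g, v in unit_a1.items()},
        mean_tau_m={g: float(np.mean(v)) for g, v in unit_tau_m.items()},
        t_statistic=cmp.statistic, p_value=cmp.p_value,
        effect_direction=cmp.effect_direction, unit_means_a1=unit_a1)
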