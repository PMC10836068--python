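"""Synthetic metabolic scenes and TCSPC acquisition simulation.

Every downstream stage (binning, masking, per-pixel fitting, mixture
statistics) is exercised on data from this module, so it emulates the
features of an in vivo NADH FLIM acquisition that those stages are
sensitive to:

* region-structured ground-truth maps of the free-NADH fraction a1
  ("brain-like" scenes with high a1 / high glycolysis, "skeletal-like"
  scenes with lower a1, unimodal or bimodal a1 fields);
* per-pixel photon-count decay histograms whose expectations follow the
  folded two-component exponential model, with independent Poisson counts;
* fluorescent-protein-like intensity channels (EGFP / mCherry surrogates)
  used only to locate the tumor by thresholding.

It deliberately does not model optics (PSF, scattering, depth
attenuation), sample motion, or melanin absorption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AcquisitionConfig
from .decay_model import DecayParams, model_bin_probabilities
from .errors import PartitionError

# Construction conventions for scene lifetimes: the short (free-NADH)
# component must sit below 1 ns and the long (bound-NADH) component in
# (0.5, 6] ns, comfortably containing the physiological 0.1-0.5 ns and
# 1-5 ns windows.
TAU1_RANGE = (0.0, 1.0)
TAU2_RANGE = (0.5, 6.0)


@dataclass
class Region:
    """One scene region: a pixel set with shared decay statistics.

    ``a1_mean``/``a1_sd`` parameterize the truncated-Gaussian draw of the
    per-pixel free fraction; ``tau1``/``tau2`` are constant over the
    region; ``intensity_scale`` is the expected photon count of the
    fluorescent-protein marker channels (relative brightness, also used to
    weight the FLIM photon budget).
    """

    label: str
    mask: np.ndarray
    a1_mean: float
    a1_sd: float
    tau1: float
    tau2: float
    intensity_scale: float

    def validate(self) -> None:
        if not 0.0 < self.a1_mean < 1.0:
            raise ValueError(
                f"region {self.label!r}: a1_mean must lie in (0, 1), "
                f"got {self.a1_mean}")
        if self.a1_sd < 0:
            raise ValueError(f"region {self.label!r}: a1_sd must be >= 0")
        if not TAU1_RANGE[0] < self.tau1 < TAU1_RANGE[1]:
            raise ValueError(
                f"region {self.label!r}: tau1 must lie in (0, 1) ns")
        if not TAU2_RANGE[0] < self.tau2 <= TAU2_RANGE[1]:
            raise ValueError(
                f"region {self.label!r}: tau2 must lie in (0.5, 6] ns")
        if self.tau1 >= self.tau2:
            raise ValueError(f"region {self.label!r}: tau1 must be < tau2")
        if self.intensity_scale < 0:
            raise ValueError(
                f"region {self.label!r}: intensity_scale must be >= 0")


@dataclass
class SceneSpec:
    """Ground-truth scene description: regions partitioning the frame."""

    regions: list[Region]
    modality: str = "unimodal"  # "unimodal" | "bimodal"
    group_label: str = ""
    seed: int = 0

    def frame_shape(self) -> tuple[int, int]:
        return self.regions[0].mask.shape

    def validate(self) -> None:
        if not self.regions:
            raise PartitionError("scene has no regions")
        if self.modality not in ("unimodal", "bimodal"):
            raise ValueError(f"unknown modality {self.modality!r}")
        shape = self.frame_shape()
        cover = np.zeros(shape, dtype=int)
        for region in self.regions:
            if region.mask.shape != shape:
                raise PartitionError(
                    f"region {region.label!r} mask shape {region.mask.shape} "
                    f"differs from frame shape {shape}")
            region.validate()
            cover += region.mask.astype(int)
        if (cover > 1).any():
            raise PartitionError("regions overlap")
        if (cover == 0).any():
            raise PartitionError(
                "regions do not cover the frame (background must be an "
                "explicit region)")


@dataclass
class ParameterMaps:
    """Per-pixel decay parameters, ground-truth or fitted.

    Invariants at valid pixels: a1 + a2 = 1, tau_m = a1*tau1 + a2*tau2,
    0 <= a1 <= 1, 0 < tau1 < tau2. ``fit_ok``/``objective_value`` are only
    present on fitted maps; unfit or unmasked pixels carry NaN.
    """

    a1: np.ndarray
    a2: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    tau_m: np.ndarray
    intensity: np.ndarray
    fit_ok: Optional[np.ndarray] = None
    objective_value: Optional[np.ndarray] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.a1.shape

    def valid_mask(self) -> np.ndarray:
        """Pixels with finite parameters (and fit_ok where present)."""
        ok = np.isfinite(self.a1)
        if self.fit_ok is not None:
            ok &= self.fit_ok
        return ok

    def validate(self, atol: float = 1e-9) -> None:
        ok = self.valid_mask()
        if not ok.any():
            return
        a1, a2 = self.a1[ok], self.a2[ok]
        t1, t2, tm = self.tau1[ok], self.tau2[ok], self.tau_m[ok]
        if not np.allclose(a1 + a2, 1.0, atol=atol, rtol=0):
            raise ValueError("a1 + a2 != 1")
        if not np.allclose(tm, a1 * t1 + a2 * t2, atol=atol, rtol=0):
            raise ValueError("tau_m != a1*tau1 + a2*tau2")
        if (a1 < 0).any() or (a1 > 1).any():
            raise ValueError("a1 outside [0, 1]")
        if (t1 <= 0).any() or (t2 <= t1).any():
            raise ValueError("lifetimes must satisfy 0 < tau1 < tau2")


@dataclass
class DecayCube:
    """TCSPC photon-count cube: (rows, cols, time bins) of integer counts."""

    counts: np.ndarray
    time_axis_ns: np.ndarray
    acquisition: AcquisitionConfig

    def validate(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-dimensional (rows, cols, bins)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integer-valued")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.time_axis_ns.size != self.counts.shape[2]:
            raise ValueError("time axis length must equal the bin count")
        if (np.diff(self.time_axis_ns) <= 0).any():
            raise ValueError("time axis must be strictly increasing")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    def total_counts(self) -> np.ndarray:
        """Per-pixel total photon count image."""
        return self.counts.sum(axis=2)


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian draws rejected outside (0, 1); sd = 0 gives constants."""
    if sd == 0.0:
        return np.full(size, mean)
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        good = (draw > 0.0) & (draw < 1.0)
        out[todo[good]] = draw[good]
        todo = todo[~good]
    return out


def build_scene(spec: SceneSpec) -> ParameterMaps:
    """Realize a ground-truth parameter map from a scene specification.

    Each pixel's a1 is drawn from its region's truncated Gaussian;
    lifetimes are constant per region; the intensity map carries the
    region's marker-channel brightness. Deterministic given ``spec.seed``.
    """
    spec.validate()
    shape = spec.frame_shape()
    rng = np.random.default_rng(spec.seed)
    a1 = np.full(shape, np.nan)
    tau1 = np.full(shape, np.nan)
    tau2 = np.full(shape, np.nan)
    intensity = np.zeros(shape)
    for region in spec.regions:
        idx = region.mask
        a1[idx] = _truncated_normal(region.a1_mean, region.a1_sd,
                                    int(idx.sum()), rng)
        tau1[idx] = region.tau1
        tau2[idx] = region.tau2
        intensity[idx] = region.intensity_scale
    a2 = 1.0 - a1
    maps = ParameterMaps(a1=a1, a2=a2, tau1=tau1, tau2=tau2,
                         tau_m=a1 * tau1 + a2 * tau2, intensity=intensity)
    maps.validate()
    return maps


def simulate_decay_cube(truth: ParameterMaps, acq: AcquisitionConfig,
                        seed: int) -> DecayCube:
    """Simulate one TCSPC acquisition of a ground-truth scene.

    Expected counts in bin j of a pixel are ``N_pix * p_j`` where ``p_j``
    is the folded (and, if configured, IRF-convolved) two-component decay
    probability and ``N_pix`` is the pixel's photon budget:
    ``acq.mean_photons_per_pixel`` scaled by the pixel's relative
    brightness (``intensity / max intensity``), so the brightest region
    hits the configured budget. Observed counts are independent Poisson
    draws; deterministic given ``seed``.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    expected = expected_decay_counts(truth, acq)
    counts = rng.poisson(expected).astype(np.uint32)
    cube = DecayCube(counts=counts, time_axis_ns=acq.time_axis_ns,
                     acquisition=acq)
    cube.validate()
    return cube


def expected_decay_counts(truth: ParameterMaps,
                          acq: AcquisitionConfig) -> np.ndarray:
    """Noiseless expected TCSPC cube (the Poisson means), float-valued."""
    shape = truth.shape
    scale = truth.intensity.max()
    if scale <= 0:
        raise ValueError("scene has no positive-intensity region")
    budget = acq.mean_photons_per_pixel * truth.intensity / scale
    expected = np.zeros(shape + (acq.n_time_bins,))
    # lifetimes are constant per region: group pixels by (tau1, tau2)
    finite = np.isfinite(truth.tau1)
    pairs = np.unique(
        np.stack([truth.tau1[finite], truth.tau2[finite]], axis=1), axis=0)
    for t1, t2 in pairs:
        sel = finite & (truth.tau1 == t1) & (truth.tau2 == t2)
        a1 = truth.a1[sel]
        # p(a1) is linear in a1 for fixed lifetimes before normalization;
        # after normalization it is a ratio, so evaluate via the two
        # component distributions
        p_short = model_bin_probabilities(
            DecayParams(1.0, t1, t2), acq)
        p_long = model_bin_probabilities(
            DecayParams(0.0, t1, t2), acq)
        # folded per-component masses inside the window differ, so the
        # mixture must be reweighted by each component's window mass
        w_short = _window_mass(t1, acq)
        w_long = _window_mass(t2, acq)
        num = (a1[:, None] * w_short * p_short[None, :]
               + (1 - a1)[:, None] * w_long * p_long[None, :])
        p = num / num.sum(axis=1, keepdims=True)
        expected[sel] = budget[sel][:, None] * p
    return expected


def _window_mass(tau: float, acq: AcquisitionConfig) -> float:
    """Folded single-exponential probability mass inside the window."""
    return ((1.0 - np.exp(-acq.window_ns / tau))
            / (1.0 - np.exp(-acq.period_ns / tau)))


def simulate_intensity_images(truth: ParameterMaps, acq: AcquisitionConfig,
                              seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the EGFP- and mCherry-like marker channels.

    Both channels are Poisson draws with per-pixel mean equal to the
    region ``intensity_scale``; they exist only so the masking stage has
    something realistic to threshold. Deterministic given ``seed``.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    egfp = rng.poisson(truth.intensity).astype(np.uint32)
    mcherry = rng.poisson(truth.intensity).astype(np.uint32)
    return egfp, mcherry


# ---------------------------------------------------------------------------
# Scene constructors used throughout tests, docs, and the demo pipeline.

def uniform_scene(shape: tuple[int, int] = (64, 64), a1_mean: float = 0.7,
                  a1_sd: float = 0.0, tau1: float = 0.3, tau2: float = 2.5,
                  intensity_scale: float = 1000.0, seed: int = 0,
                  group_label: str = "") -> SceneSpec:
    """Single-region scene covering the whole frame."""
    mask = np.ones(shape, dtype=bool)
    region = Region("tissue", mask, a1_mean, a1_sd, tau1, tau2,
                    intensity_scale)
    return SceneSpec([region], modality="unimodal", group_label=group_label,
                     seed=seed)


def bimodal_scene(shape: tuple[int, int] = (64, 64),
                  a1_means: tuple[float, float] = (0.55, 0.75),
                  a1_sd: float = 0.02, tau1: float = 0.3, tau2: float = 2.5,
                  intensity_scale: float = 1000.0, seed: int = 0,
                  group_label: str = "") -> SceneSpec:
    """Two equal half-frame regions with distinct a1 means.

    Emulates a tumor containing two coexisting metabolic subpopulations,
    the situation in which the pooled a1 histogram is bimodal.
    """
    rows, cols = shape
    left = np.zeros(shape, dtype=bool)
    left[:, : cols // 2] = True
    lo = Region("oxphos-shifted", left, a1_means[0], a1_sd, tau1, tau2,
                intensity_scale)
    hi = Region("glycolytic", ~left, a1_means[1], a1_sd, tau1, tau2,
                intensity_scale)
    return SceneSpec([lo, hi], modality="bimodal", group_label=group_label,
                     seed=seed)


def tumor_scene(shape: tuple[int, int] = (64, 64), a1_mean: float = 0.7,
                a1_sd: float = 0.03, tau1: float = 0.3, tau2: float = 2.5,
                tumor_intensity: float = 1000.0,
                background_intensity: float = 10.0,
                background_a1: float = 0.5, radius_frac: float = 0.35,
                seed: int = 0, group_label: str = "") -> SceneSpec:
    """Bright circular tumor on a dim autofluorescent background.

    The brightness contrast between ``tumor_intensity`` and
    ``background_intensity`` is what the masking stage thresholds on.
    """
    rows, cols = shape
    rr, cc = np.mgrid[:rows, :cols]
    radius = radius_frac * min(rows, cols)
    tumor_mask = (rr - rows / 2) ** 2 + (cc - cols / 2) ** 2 <= radius**2
    tumor = Region("tumor", tumor_mask, a1_mean, a1_sd, tau1, tau2,
                   tumor_intensity)
    bg = Region("background", ~tumor_mask, background_a1, a1_sd, tau1, tau2,
                background_intensity)
    return SceneSpec([tumor, bg], modality="unimodal",
                     group_label=group_label, seed=seed)
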