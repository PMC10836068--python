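"""Per-pixel two-component decay fitting: binning, masking, fit, maps.

Mirrors the analysis applied to in vivo NADH FLIM data: photon counts are
first spatially binned ("bin of 4": each pixel's decay becomes the sum
over its 2x2 neighborhood, raising the counts per decay), tumor pixels are
selected by thresholding the fluorescent-protein intensity channels, and
each selected pixel's histogram is fitted to the folded two-component
exponential with the constraint a1 + a2 = 1 enforced by parameterizing a1
alone.

The fit objective is Poisson maximum likelihood by default (TCSPC counts
are Poisson); a Neyman-weighted least-squares objective is provided as a
faster alternative and as the asymptotic-equivalence cross-check. Under
either objective the total amplitude is profiled out analytically, so the
optimizer works in the 3-parameter space (a1, tau1, tau2) with box bounds
derived from the physiological free (0.1-0.5 ns) and bound (1-5 ns)
NADH lifetime windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from skimage.filters import threshold_otsu

from .config import AcquisitionConfig
from .decay_model import (DecayParams, mean_lifetime,
                          model_probabilities_and_jacobian)
from .errors import EmptySelectionError
from .synth import DecayCube, ParameterMaps

_TINY = 1e-300


@dataclass
class ROIMask:
    """Boolean pixel-inclusion image with the rule that produced it."""

    include: np.ndarray
    provenance: str = ""

    @property
    def n_selected(self) -> int:
        return int(self.include.sum())

    @property
    def empty(self) -> bool:
        return not self.include.any()


@dataclass
class FitOptions:
    """Configuration of the per-pixel decay fit.

    Initialization defaults (0.3 ns / 2.5 ns) are the midpoints of the
    free and bound NADH lifetime windows; bounds extend slightly beyond
    those windows so the optimizer is not pinned at physiological edges.
    ``min_photons`` guards identifiability: below ~100 counts a
    two-component decay is practically unresolvable and the pixel is
    flagged unfit rather than fitted. ``bin_window`` applies the
    neighborhood-sum binning before fitting (2 reproduces "bin of 4").
    """

    objective: str = "poisson_mle"  # or "weighted_least_squares"
    init_a1: float = 0.5
    init_tau1: float = 0.3
    init_tau2: float = 2.5
    a1_bounds: tuple[float, float] = (0.0, 1.0)
    tau1_bounds: tuple[float, float] = (0.05, 1.0)
    tau2_bounds: tuple[float, float] = (0.5, 6.0)
    max_iterations: int = 200
    convergence_tol: float = 1e-9
    min_photons: int = 100
    bin_window: int = 2

    def __post_init__(self) -> None:
        if self.objective not in ("poisson_mle", "weighted_least_squares"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if not (0 <= self.a1_bounds[0] < self.a1_bounds[1] <= 1):
            raise ValueError("a1 bounds must satisfy 0 <= lo < hi <= 1")
        if not (0 < self.tau1_bounds[0] < self.tau1_bounds[1]):
            raise ValueError("tau1 bounds must be positive and ordered")
        if not (0 < self.tau2_bounds[0] < self.tau2_bounds[1]):
            raise ValueError("tau2 bounds must be positive and ordered")
        if self.min_photons < 0:
            raise ValueError("min_photons must be >= 0")


@dataclass
class PixelFitResult:
    """Outcome of one per-pixel fit."""

    params: Optional[DecayParams]
    fit_ok: bool
    objective_value: float
    n_iterations: int
    total_counts: float
    message: str = ""


def spatial_bin(cube: DecayCube, window: int = 2,
                mode: str = "sliding") -> DecayCube:
    """Sum decay histograms over a ``window x window`` pixel neighborhood.

    ``mode="sliding"`` (the "bin of 4" behavior for window=2) keeps the
    frame size: each output pixel is the sum over the window anchored at
    that pixel, with edge pixels using the available sub-window. Counts
    never decrease. ``mode="block"`` sums non-overlapping blocks instead,
    shrinking the frame and conserving the grand total exactly (frame
    dimensions must be divisible by the window).
    """
    cube.validate()
    if window < 1:
        raise ValueError("window must be >= 1")
    c = cube.counts
    if mode == "sliding":
        out = c.astype(np.int64)
        # separable: sum forward-shifted copies along rows, then columns
        acc = out.copy()
        for k in range(1, window):
            acc[:-k] += out[k:]
        out = acc
        acc = out.copy()
        for k in range(1, window):
            acc[:, :-k] += out[:, k:]
        binned = acc
    elif mode == "block":
        rows, cols, nbins = c.shape
        if rows % window or cols % window:
            raise ValueError(
                "block mode requires frame dimensions divisible by window")
        binned = (c.reshape(rows // window, window, cols // window, window,
                            nbins).astype(np.int64).sum(axis=(1, 3)))
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return DecayCube(counts=binned.astype(np.uint64),
                     time_axis_ns=cube.time_axis_ns,
                     acquisition=cube.acquisition)


def intensity_mask(intensity: np.ndarray, rule="otsu") -> ROIMask:
    """Select pixels by thresholding a marker-intensity image.

    ``rule`` is ``"otsu"``, ``("fixed", value)``, or ``("quantile", q)``.
    Pixels at or above the threshold are included. An empty selection is
    legal but warns; downstream value extraction raises an explicit
    empty-selection error.
    """
    intensity = np.asarray(intensity)
    if (intensity < 0).any():
        raise ValueError("intensity must be nonnegative")
    if rule == "otsu" or rule == ("otsu",):
        thresh = float(threshold_otsu(intensity.astype(float)))
        provenance = f"otsu(threshold={thresh:.6g})"
    else:
        kind, value = rule
        if kind == "fixed":
            thresh = float(value)
            provenance = f"fixed(threshold={thresh:.6g})"
        elif kind == "quantile":
            if not 0.0 <= value <= 1.0:
                raise ValueError("quantile must lie in [0, 1]")
            thresh = float(np.quantile(intensity, value))
            provenance = f"quantile(q={value}, threshold={thresh:.6g})"
        else:
            raise ValueError(f"unknown threshold rule {kind!r}")
    include = intensity >= thresh
    mask = ROIMask(include=include, provenance=provenance)
    if mask.empty:
        warnings.warn("intensity mask selected no pixels", stacklevel=2)
    return mask


def _poisson_nll(x: np.ndarray, y: np.ndarray, acq: AcquisitionConfig):
    """Profiled Poisson negative log-likelihood and gradient.

    With model means A * p(theta), sum_j p_j = 1, the amplitude MLE is the
    total count, leaving -sum_j y_j log p_j(theta) (up to constants).
    """
    p, jac = model_probabilities_and_jacobian(x[0], x[1], x[2], acq)
    np.clip(p, _TINY, None, out=p)
    f = -float(y @ np.log(p))
    g = -(jac @ (y / p))
    return f, g


def _wls_objective(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   acq: AcquisitionConfig):
    """Neyman-weighted least squares with the amplitude profiled out."""
    p, jac = model_probabilities_and_jacobian(x[0], x[1], x[2], acq)
    wp = w * p
    denom = float(p @ wp)
    amp = float(y @ wp) / denom
    r = y - amp * p
    f = float(r @ (w * r))
    # d amp/d theta via quotient rule; dr = -(damp p + amp dp)
    damp = (jac @ (w * y) - 2.0 * amp * (jac @ wp)) / denom
    g = -2.0 * ((jac * amp + np.outer(damp, p)) @ (w * r))
    return f, g


# fallback starting points tried when the optimizer pins both lifetimes
# at the crossing corner of their bounds (label-switching local minimum)
_FALLBACK_STARTS = ((0.7, 0.4, 1.5), (0.3, 0.2, 3.5), (0.6, 0.45, 1.1))


def _minimize(fun, x0, args, bounds, opts: FitOptions):
    return optimize.minimize(
        fun, np.asarray(x0, dtype=float), args=args, jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": opts.max_iterations,
                 "ftol": opts.convergence_tol, "gtol": 1e-10})


def _minimize_with_restarts(fun, x0, args, bounds, opts: FitOptions):
    """L-BFGS-B with corner-escape restarts.

    When the two-component model is weakly identified the optimizer can
    converge with tau1 pinned at its upper bound and tau2 at its lower
    bound (the components trying to swap labels). That corner is detected
    and the fit is retried from a few spread-out starting points, keeping
    the best objective.
    """
    res = _minimize(fun, x0, args, bounds, opts)
    pinned = (res.x[1] >= bounds[1][1] - 1e-3
              and res.x[2] <= bounds[2][0] + 1e-3)
    if pinned:
        for start in _FALLBACK_STARTS:
            alt = _minimize(fun, start, args, bounds, opts)
            if alt.fun < res.fun:
                res = alt
    return res


def fit_pixel(histogram: np.ndarray, acq: AcquisitionConfig,
              opts: FitOptions = FitOptions()) -> PixelFitResult:
    """Fit one decay histogram to the constrained two-component model.

    Returns the optimum of the configured objective over (a1, tau1, tau2)
    with a1 + a2 = 1 built in; the fitted lifetimes are swapped (and a1
    relabeled 1 - a1) if the optimizer crosses their ordering. Histograms
    below ``opts.min_photons`` total counts are flagged unfit without
    raising.

    The weighted-least-squares objective starts from observed-count
    (Neyman) weights and then iterates twice with weights recomputed from
    the fitted model, which removes the small-count bias of pure Neyman
    weighting and brings the estimate into asymptotic agreement with the
    Poisson MLE.
    """
    y = np.asarray(histogram, dtype=float)
    total = float(y.sum())
    if total < opts.min_photons:
        return PixelFitResult(None, False, np.nan, 0, total,
                              "below min_photons")
    x0 = np.array([opts.init_a1, opts.init_tau1, opts.init_tau2])
    bounds = [opts.a1_bounds, opts.tau1_bounds, opts.tau2_bounds]
    if opts.objective == "poisson_mle":
        res = _minimize_with_restarts(_poisson_nll, x0, (y, acq), bounds,
                                      opts)
    else:
        w = 1.0 / np.maximum(y, 1.0)
        res = _minimize_with_restarts(_wls_objective, x0, (y, w, acq),
                                      bounds, opts)
        for _ in range(2):  # model-based reweighting
            p, _ = model_probabilities_and_jacobian(*res.x, acq)
            wp = w * p
            amp = float(y @ wp) / float(p @ wp)
            w = 1.0 / np.maximum(amp * p, 1.0)
            res = _minimize_with_restarts(_wls_objective, res.x, (y, w, acq),
                                          bounds, opts)
    a1, tau1, tau2 = res.x
    if tau1 > tau2:  # relabel so tau1 is always the short component
        tau1, tau2 = tau2, tau1
        a1 = 1.0 - a1
    if tau1 == tau2:
        return PixelFitResult(None, False, float(res.fun), res.nit, total,
                              "degenerate lifetimes")
    params = DecayParams(a1=float(a1), tau1=float(tau1), tau2=float(tau2))
    return PixelFitResult(params, bool(res.success), float(res.fun),
                          int(res.nit), total, res.message)


def fit_cube(cube: DecayCube, mask: ROIMask, acq: AcquisitionConfig,
             opts: FitOptions = FitOptions()) -> ParameterMaps:
    """Fit every masked pixel of a cube and assemble parameter maps.

    Applies the spatial binning configured in ``opts`` first, then
    ``fit_pixel`` per masked pixel. Unmasked or unfit pixels hold NaN in
    every float map and False in ``fit_ok``.
    """
    if mask.include.shape != cube.frame_shape:
        raise ValueError("mask shape does not match cube frame")
    if mask.empty:
        raise EmptySelectionError("mask selects no pixels")
    binned = spatial_bin(cube, opts.bin_window) if opts.bin_window > 1 else cube
    shape = cube.frame_shape
    nan = np.full(shape, np.nan)
    maps = ParameterMaps(a1=nan.copy(), a2=nan.copy(), tau1=nan.copy(),
                         tau2=nan.copy(), tau_m=nan.copy(),
                         intensity=binned.total_counts().astype(float),
                         fit_ok=np.zeros(shape, dtype=bool),
                         objective_value=nan.copy())
    for r, c in zip(*np.nonzero(mask.include)):
        result = fit_pixel(binned.counts[r, c], acq, opts)
        maps.objective_value[r, c] = result.objective_value
        if result.params is None:
            continue
        p = result.params
        maps.a1[r, c] = p.a1
        maps.a2[r, c] = p.a2
        maps.tau1[r, c] = p.tau1
        maps.tau2[r, c] = p.tau2
        maps.tau_m[r, c] = mean_lifetime(p)
        maps.fit_ok[r, c] = result.fit_ok
    return maps
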