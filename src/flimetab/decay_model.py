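"""Two-component fluorescence-decay model shared by simulator and fitter.

NADH fluorescence decays as a mixture of a short-lifetime (free NADH,
~0.1-0.5 ns) and a long-lifetime (protein-bound NADH, ~1-5 ns) exponential:

    I(t) = a1 * exp(-t / tau1) + a2 * exp(-t / tau2),    a1 + a2 = 1

At an 80 MHz repetition rate the 12.5 ns inter-pulse period is short
relative to 5 tau of the bound component, so fluorescence excited by
earlier pulses wraps into the current measurement window ("incomplete
decay"). The folded per-bin photon-arrival probabilities are available in
closed form: a single exponential folded over period T keeps its shape but
its total weight inside one period is scaled by 1 / (1 - exp(-T/tau)),
via the geometric series over wrapped periods. Bin probabilities are exact
integrals of the exponential over each bin, not midpoint samples, so they
stay exact at coarse bin widths.

The amplitude-weighted mean lifetime is tau_m = a1*tau1 + a2*tau2; a higher
free fraction a1 (more glycolytic metabolism) gives a shorter tau_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AcquisitionConfig


@dataclass(frozen=True)
class DecayParams:
    """Normalized two-component decay parameters.

    ``a1`` is the fractional amplitude of the short (free-NADH) component;
    ``a2 = 1 - a1`` is implied. Lifetimes are in nanoseconds with
    ``0 < tau1 < tau2``.
    """

    a1: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a1 <= 1.0:
            raise ValueError(f"a1 must lie in [0, 1], got {self.a1}")
        if not 0.0 < self.tau1 < self.tau2:
            raise ValueError(
                f"lifetimes must satisfy 0 < tau1 < tau2, got "
                f"tau1={self.tau1}, tau2={self.tau2}"
            )

    @property
    def a2(self) -> float:
        return 1.0 - self.a1


def biexp_decay(t, params: DecayParams):
    """Evaluate I(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2) at times ``t`` (ns).

    The value at t = 0 is exactly 1 because a1 + a2 = 1. Negative times are
    a domain error.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("decay times must be >= 0")
    out = params.a1 * np.exp(-t / params.tau1) + params.a2 * np.exp(-t / params.tau2)
    return out if out.ndim else float(out)


def mean_lifetime(params: DecayParams) -> float:
    """Amplitude-weighted mean lifetime tau_m = a1*tau1 + a2*tau2 in ns."""
    return params.a1 * params.tau1 + params.a2 * params.tau2


def _component_bin_weights(tau: float, edges: np.ndarray, period: float,
                           fold: bool, grad: bool = False):
    """Per-bin arrival weights of one exponential component.

    Returns the (unnormalized within the window, but correctly
    inter-component weighted) probability mass per bin, i.e. the integral
    over each bin of the unit-normalized single-exponential pdf, folded
    over ``period`` when ``fold``. With folding the geometric series gives
    a 1/(1 - exp(-period/tau)) prefactor. When ``grad``, also returns the
    derivative with respect to tau.
    """
    e = np.exp(-edges / tau)
    u = e[:-1] - e[1:]
    if fold and np.isfinite(period):
        ep = np.exp(-period / tau)
        c = 1.0 - ep
    else:
        ep = 0.0
        c = 1.0
    w = u / c
    if not grad:
        return w
    du = (edges[:-1] * e[:-1] - edges[1:] * e[1:]) / tau**2
    dc = -(period / tau**2) * ep if (fold and np.isfinite(period)) else 0.0
    dw = du / c - u * dc / c**2
    return w, dw


def bin_probabilities(params: DecayParams, acq: AcquisitionConfig,
                      fold: bool = True) -> np.ndarray:
    """Photon-arrival probability per time bin, summing to 1.

    With ``fold=True`` (default) the decay is wrapped over the repetition
    period by the closed-form geometric summation; with ``fold=False`` the
    plain bin-integrated two-component decay is normalized over the window.
    """
    edges = acq.bin_edges_ns
    w1 = _component_bin_weights(params.tau1, edges, acq.period_ns, fold)
    w2 = _component_bin_weights(params.tau2, edges, acq.period_ns, fold)
    m = params.a1 * w1 + params.a2 * w2
    return m / m.sum()


def folded_bin_probabilities(params: DecayParams,
                             acq: AcquisitionConfig) -> np.ndarray:
    """Bin probabilities under periodic excitation (incomplete-decay model)."""
    return bin_probabilities(params, acq, fold=True)


def _gaussian_kernel(irf_sigma: float, acq: AcquisitionConfig) -> np.ndarray:
    """Discretized, periodically wrapped Gaussian IRF kernel summing to 1."""
    n = acq.n_time_bins
    centers = (np.arange(n) + 0.5) * acq.bin_width_ns
    # signed circular offset of every bin from t=0 within the window
    offset = np.minimum(centers, acq.window_ns - centers)
    k = np.exp(-0.5 * (offset / irf_sigma) ** 2)
    return k / k.sum()


def convolve_irf(bin_probs: np.ndarray, irf_sigma: float,
                 acq: AcquisitionConfig) -> np.ndarray:
    """Circularly convolve bin probabilities with a Gaussian IRF.

    Circular (periodic) convolution matches the folded model's periodic
    boundary. ``irf_sigma = 0`` returns the input unchanged; the output
    always sums to the input's total.
    """
    if irf_sigma < 0:
        raise ValueError("irf_sigma must be >= 0")
    bin_probs = np.asarray(bin_probs, dtype=float)
    if irf_sigma == 0.0:
        return bin_probs.copy()
    kernel = _gaussian_kernel(irf_sigma, acq)
    out = np.fft.irfft(np.fft.rfft(bin_probs) * np.fft.rfft(kernel),
                       n=bin_probs.size)
    # fft round-off can leave tiny negatives on near-empty bins
    np.maximum(out, 0.0, out=out)
    return out * (bin_probs.sum() / out.sum())


def model_bin_probabilities(params: DecayParams,
                            acq: AcquisitionConfig) -> np.ndarray:
    """Full forward model: folded bin probabilities, IRF-convolved if set."""
    p = folded_bin_probabilities(params, acq)
    if acq.irf_sigma_ns > 0:
        p = convolve_irf(p, acq.irf_sigma_ns, acq)
    return p


def model_probabilities_and_jacobian(a1: float, tau1: float, tau2: float,
                                     acq: AcquisitionConfig):
    """Forward-model bin probabilities and their gradient.

    Returns ``(p, J)`` where ``p`` has shape (n_bins,) and ``J`` shape
    (3, n_bins) holding dp/da1, dp/dtau1, dp/dtau2. Used by the per-pixel
    maximum-likelihood fitter; IRF convolution is linear so the gradient is
    convolved with the same kernel.
    """
    edges = acq.bin_edges_ns
    w1, dw1 = _component_bin_weights(tau1, edges, acq.period_ns, True, grad=True)
    w2, dw2 = _component_bin_weights(tau2, edges, acq.period_ns, True, grad=True)
    m = a1 * w1 + (1.0 - a1) * w2
    dm = np.stack([w1 - w2, a1 * dw1, (1.0 - a1) * dw2])
    s = m.sum()
    ds = dm.sum(axis=1)
    p = m / s
    jac = dm / s - np.outer(ds, m) / s**2
    if acq.irf_sigma_ns > 0:
        kernel_f = np.fft.rfft(_gaussian_kernel(acq.irf_sigma_ns, acq))
        p = np.fft.irfft(np.fft.rfft(p) * kernel_f, n=p.size)
        np.maximum(p, 0.0, out=p)
        jac = np.fft.irfft(np.fft.rfft(jac, axis=1) * kernel_f, n=p.size, axis=1)
    return p, jac
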