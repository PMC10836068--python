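"""Acquisition configuration for simulated TCSPC FLIM measurements.

The defaults emulate a two-photon FLIM acquisition at 80 MHz pulse
repetition: the 12.5 ns inter-pulse period is divided into 256 time bins.
Frame geometry defaults to 64 x 64 so the full pipeline runs at desk scale;
real acquisitions of this kind are typically 512 x 512 and every stage
accepts that size as well.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError

NS_PER_S = 1e9


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing, geometry, and photon-budget description of one acquisition.

    Parameters
    ----------
    repetition_rate_hz:
        Pulsed-excitation repetition rate in Hz (default 80 MHz).
    n_time_bins:
        Number of TCSPC histogram bins spanning the measurement window.
    bin_width_ns:
        Width of one time bin in nanoseconds. The measurement window
        ``n_time_bins * bin_width_ns`` must not exceed the repetition
        period.
    frame_shape:
        (rows, cols) of the image frame.
    irf_sigma_ns:
        Standard deviation of the Gaussian instrument response in ns;
        0 means a delta IRF (no temporal blur).
    mean_photons_per_pixel:
        Expected total photon count in the brightest region's pixels.
    """

    repetition_rate_hz: float = 80e6
    n_time_bins: int = 256
    bin_width_ns: float = 12.5 / 256
    frame_shape: tuple[int, int] = (64, 64)
    irf_sigma_ns: float = 0.0
    mean_photons_per_pixel: float = 5000.0

    def __post_init__(self) -> None:
        if self.repetition_rate_hz <= 0:
            raise ConfigurationError("repetition_rate_hz must be positive")
        if self.n_time_bins <= 0 or int(self.n_time_bins) != self.n_time_bins:
            raise ConfigurationError("n_time_bins must be a positive integer")
        if self.bin_width_ns <= 0:
            raise ConfigurationError("bin_width_ns must be positive")
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError("frame_shape entries must be positive")
        if self.irf_sigma_ns < 0:
            raise ConfigurationError("irf_sigma_ns must be >= 0")
        if self.mean_photons_per_pixel <= 0:
            raise ConfigurationError("mean_photons_per_pixel must be positive")
        # small float slop so 256 bins exactly tiling 12.5 ns validate
        if self.window_ns > self.period_ns * (1 + 1e-12):
            raise ConfigurationError(
                f"measurement window {self.window_ns:.6g} ns exceeds the "
                f"repetition period {self.period_ns:.6g} ns"
            )

    @property
    def period_ns(self) -> float:
        """Repetition period in nanoseconds."""
        return NS_PER_S / self.repetition_rate_hz

    @property
    def window_ns(self) -> float:
        """Total measurement window covered by the time bins, in ns."""
        return self.n_time_bins * self.bin_width_ns

    @property
    def bin_edges_ns(self) -> np.ndarray:
        """Bin edges, length ``n_time_bins + 1``, starting at t = 0."""
        return np.arange(self.n_time_bins + 1) * self.bin_width_ns

    @property
    def time_axis_ns(self) -> np.ndarray:
        """Left edge of each time bin (bin 0 starts at t = 0)."""
        return np.arange(self.n_time_bins) * self.bin_width_ns

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        return cls(**d)
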