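"""Welch power spectral density and relative band power.

Used to establish that topology differences between groups are not
trivially explained by band-power differences: relative power in each
canonical band is the fraction of Welch-estimated power it carries
within the analysed [1, 30) Hz range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import BandDefinition

__all__ = ["PowerSpectrum", "welch_psd", "relative_band_power"]

#: Denominator range for relative power: union of the four canonical bands.
DEFAULT_TOTAL_RANGE: tuple[float, float] = (1.0, 30.0)


@dataclass
class PowerSpectrum:
    """One-sided Welch PSD per channel.

    frequencies : (n_freqs,) Hz grid from 0 to fs/2
    density : (n_channels, n_freqs) power per Hz
    """

    frequencies: np.ndarray
    density: np.ndarray
    nperseg: int
    overlap: float
    window: str

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("spectral density must be nonnegative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def welch_psd(
    data: np.ndarray,
    fs: float,
    nperseg: int = 512,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PowerSpectrum:
    """Welch's averaged modified periodogram of one epoch (channels x samples).

    Defaults: 2 s Hamming segments with 50% overlap at 256 Hz, i.e.
    0.5 Hz resolution and 7 averaged segments per 8 s epoch.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[-1] < nperseg:
        raise ValueError(
            f"segment length {nperseg} exceeds epoch length {data.shape[-1]}"
        )
    freqs, dens = signal.welch(
        data,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        axis=-1,
    )
    return PowerSpectrum(
        frequencies=freqs, density=dens, nperseg=nperseg, overlap=overlap, window=window
    )


def relative_band_power(
    psd: PowerSpectrum,
    band: BandDefinition,
    total_range: tuple[float, float] = DEFAULT_TOTAL_RANGE,
) -> float:
    """Fraction of total power (channel sum) in [band.low, band.high).

    Power is summed over frequency bins with ``low <= f < high`` so the
    four canonical bands partition the default [1, 30) denominator
    exactly and their relative powers sum to 1.
    """
    f = psd.frequencies
    lo, hi = total_range
    if band.low < lo or band.high > hi:
        raise ValueError(
            f"band [{band.low}, {band.high}) lies outside the analysed range [{lo}, {hi})"
        )
    band_mask = (f >= band.low) & (f < band.high)
    total_mask = (f >= lo) & (f < hi)
    total = float(psd.density[:, total_mask].sum())
    if total <= 0:
        raise ValueError("total power in the analysed range is zero; relative power undefined")
    return float(psd.density[:, band_mask].sum()) / total
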