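"""Turn raw multichannel recordings into band-filtered epoch sets.

The preprocessing chain mirrors a standard resting-state EEG protocol:
common-average re-referencing over a designated channel set, removal of
bad channels, extraction of consecutive fixed-length epochs from the start
of the recording, and zero-phase band-pass filtering into the classical
delta/theta/alpha/beta bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "BANDS",
    "Recording",
    "EpochSet",
    "rereference_common_average",
    "drop_bad_channels",
    "extract_epochs",
    "bandpass_filter",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [low, high) in Hz.

    The half-open convention resolves the shared 4 / 8 / 13 Hz boundaries
    between adjacent canonical bands, so the four bands partition [1, 30).
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high})"
            )


#: Canonical EEG band set: delta [1,4), theta [4,8), alpha [8,13), beta [13,30) Hz.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


@dataclass
class Recording:
    """A labelled multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in physical units (conventionally microvolts).
    labels : tuple of str
        Unique channel names, one per row of ``data``.
    fs : float
        Sampling rate in Hz.
    bad_channels : tuple of str
        Channels to be removed before connectivity analysis.
    reference_exclusions : tuple of str
        Channels excluded from the common-average reference computation
        (they are still re-referenced themselves).
    """

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float
    bad_channels: tuple[str, ...] = ()
    reference_exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        self.bad_channels = tuple(self.bad_channels)
        self.reference_exclusions = tuple(self.reference_exclusions)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """A block of equal-length epochs: shape (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float
    band: BandDefinition | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count does not match channel axis")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_length(self) -> int:
        return self.data.shape[2]


def rereference_common_average(rec: Recording) -> Recording:
    """Re-reference to the common average of the non-excluded channels.

    At every sample the mean over channels *not* in
    ``rec.reference_exclusions`` is subtracted from **every** channel
    (excluded channels included), so the included-channel mean is zero
    afterwards. Idempotent.
    """
    included = [i for i, lab in enumerate(rec.labels) if lab not in rec.reference_exclusions]
    if len(included) < 2:
        raise ValueError(
            "common-average reference needs at least 2 channels outside "
            f"reference_exclusions; have {len(included)}"
        )
    car = rec.data[included].mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - car)


def drop_bad_channels(rec: Recording) -> Recording:
    """Remove ``rec.bad_channels`` from the data and label set.

    Bad labels that are not present are ignored with a logged warning.
    """
    present = set(rec.labels)
    missing = [b for b in rec.bad_channels if b not in present]
    if missing:
        logger.warning("bad channels not found in recording, ignored: %s", missing)
    keep = [i for i, lab in enumerate(rec.labels) if lab not in rec.bad_channels]
    return replace(
        rec,
        data=rec.data[keep],
        labels=tuple(rec.labels[i] for i in keep),
        bad_channels=(),
    )


def extract_epochs(rec: Recording, n_epochs: int, epoch_length: int) -> EpochSet:
    """Cut the first ``n_epochs`` consecutive, non-overlapping epochs.

    Sample values are copied exactly; no resampling or windowing.
    """
    needed = n_epochs * epoch_length
    if rec.n_samples < needed:
        raise ValueError(
            f"recording too short: need {needed} samples "
            f"({n_epochs} epochs x {epoch_length}), have {rec.n_samples}"
        )
    block = rec.data[:, :needed]
    epochs = np.ascontiguousarray(
        block.reshape(rec.n_channels, n_epochs, epoch_length).transpose(1, 0, 2)
    )
    return EpochSet(data=epochs, labels=rec.labels, fs=rec.fs)


def bandpass_filter(epochs: EpochSet, band: BandDefinition, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass filtering, per epoch and channel.

    A 4th-order Butterworth applied forward-backward (``sosfiltfilt``,
    effective order 8) keeps phase intact, which matters for the
    phase-based connectivity downstream.
    """
    nyq = epochs.fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz is at or above Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [band.low, band.high], btype="bandpass", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(data=filtered, labels=epochs.labels, fs=epochs.fs, band=band)
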