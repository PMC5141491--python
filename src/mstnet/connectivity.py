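"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute mean of the sign of the sine
of their instantaneous phase difference,

    PLI = | < sign( sin(phi_x(t) - phi_y(t)) ) >_t |  in [0, 1].

It measures the *asymmetry* of the phase-difference distribution: a
distribution symmetric around 0 or pi — exactly what instantaneous
volume-conduction mixing produces — gives PLI 0, while a consistent
nonzero lag gives PLI 1. Phases come from the analytic signal (Hilbert
transform) of band-limited data, and a PLI adjacency matrix is computed
independently for every epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import BandDefinition, EpochSet

__all__ = [
    "PhaseSeries",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
    "global_mean_pli",
    "mean_upper_triangle",
]


@dataclass
class PhaseSeries:
    """Instantaneous phases per epoch/channel/sample, wrapped to (-pi, pi].

    ``flat`` marks zero-variance (epoch, channel) entries whose phase is
    undefined; their phases are set to 0 and their PLI rows are zeroed.
    """

    phases: np.ndarray  # (n_epochs, n_channels, n_samples)
    labels: tuple[str, ...]
    band: BandDefinition | None
    flat: np.ndarray  # (n_epochs, n_channels) bool


@dataclass
class ConnectivityMatrix:
    """Symmetric per-epoch PLI matrix with zero diagonal, entries in [0, 1]."""

    weights: np.ndarray
    labels: tuple[str, ...]
    band: BandDefinition | None = None
    epoch_index: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if w.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix dimension")
        if np.any(np.isnan(w)):
            raise ValueError("connectivity matrix contains NaN")
        if not np.allclose(w, w.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectivity matrix must have zero diagonal")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("PLI entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def instantaneous_phase(epochs: EpochSet) -> PhaseSeries:
    """Analytic-signal phase of each channel in each epoch.

    For a pure cosine the phase advances by ``2*pi*f/fs`` per sample.
    Constant (zero-variance) channels have no defined phase; they are
    flagged, warned about, and assigned phase 0.
    """
    data = epochs.data
    flat = data.std(axis=-1) == 0
    if flat.any():
        bad = sorted({epochs.labels[c] for _, c in zip(*np.nonzero(flat))})
        warnings.warn(
            f"zero-variance channel(s) {bad}: phase undefined, PLI set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    phases = np.angle(hilbert(data, axis=-1))
    phases[flat] = 0.0
    return PhaseSeries(phases=phases, labels=epochs.labels, band=epochs.band, flat=flat)


def pli_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLI between two phase vectors.

    Samples where the phase difference is exactly 0 or pi contribute
    sign 0, so identical channels give PLI exactly 0.
    """
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError(f"phase vectors differ in shape: {phase_x.shape} vs {phase_y.shape}")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(np.sin(phase_x - phase_y)))))


def pli_matrix(epochs: EpochSet, edge_trim: int = 0) -> list[ConnectivityMatrix]:
    """Per-epoch PLI adjacency matrices over all channel pairs.

    ``edge_trim`` drops that many samples at each epoch edge before phase
    statistics are formed (default 0), a guard against filter/Hilbert
    edge effects on short epochs.
    """
    if epochs.n_channels < 2:
        raise ValueError("PLI matrix needs at least 2 channels")
    ps = instantaneous_phase(epochs)
    phases = ps.phases
    if edge_trim:
        if 2 * edge_trim >= phases.shape[-1]:
            raise ValueError("edge_trim removes all samples")
        phases = phases[..., edge_trim:-edge_trim]
    out: list[ConnectivityMatrix] = []
    for e in range(epochs.n_epochs):
        p = phases[e]
        diff = p[:, None, :] - p[None, :, :]
        w = np.abs(np.mean(np.sign(np.sin(diff)), axis=-1))
        np.fill_diagonal(w, 0.0)
        w[ps.flat[e], :] = 0.0
        w[:, ps.flat[e]] = 0.0
        w = 0.5 * (w + w.T)  # exact symmetry despite float asymmetry of sin
        out.append(
            ConnectivityMatrix(weights=w, labels=epochs.labels, band=epochs.band, epoch_index=e)
        )
    return out


def mean_upper_triangle(matrix: ConnectivityMatrix) -> float:
    """Mean of the strictly-upper-triangle entries of one matrix."""
    w = matrix.weights
    iu = np.triu_indices(w.shape[0], k=1)
    return float(w[iu].mean())


def global_mean_pli(matrices: list[ConnectivityMatrix]) -> float:
    """Global mean PLI: upper-triangle mean per epoch, then mean over epochs."""
    if not matrices:
        raise ValueError("need at least one connectivity matrix")
    dims = {m.n_channels for m in matrices}
    if len(dims) > 1:
        raise ValueError(f"matrices differ in dimension: {sorted(dims)}")
    return float(np.mean([mean_upper_triangle(m) for m in matrices]))
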