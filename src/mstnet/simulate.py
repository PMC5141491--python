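"""Synthetic resting-state cohorts with known coupling topology.

The generator produces multichannel narrowband oscillatory recordings in
which the *phase* relationships between channels follow a known spanning
tree: along each tree edge the child channel's phase is continuously
nudged toward the parent's phase plus a fixed nonzero lag (a
Kuramoto-Sakaguchi style diffusive coupling), while uncoupled channels
drift independently. Instantaneous (zero-lag) volume-conduction mixing is
applied separately, so the robustness of lag-based connectivity measures
to such mixing can be probed against ground truth.

A cohort couples topology to a clinical covariate: control subjects get a
star-like coupling tree, patient subjects a tree interpolated toward a
path, with the interpolation shift increasing with a disability score
(0-48, higher = more disabled). This realises, with known ground truth,
the centralized-to-decentralized network reorganization axis that the
downstream tree statistics are designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .montage import default_labels
from .preprocess import Recording

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "Subject",
    "make_interpolated_tree",
    "generate_recording",
    "apply_volume_conduction",
    "mixing_matrix",
    "generate_cohort",
]

Edge = tuple[int, int]


def _check_tree(n_channels: int, edges: tuple[Edge, ...]) -> None:
    """Validate that ``edges`` is a spanning tree on ``n_channels`` nodes."""
    if len(edges) != n_channels - 1:
        raise ValueError(
            f"a spanning tree on {n_channels} nodes has {n_channels - 1} edges, got {len(edges)}"
        )
    parent = list(range(n_channels))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        if not (0 <= u < n_channels and 0 <= v < n_channels):
            raise ValueError(f"edge ({u},{v}) out of range for {n_channels} channels")
        ru, rv = find(u), find(v)
        if ru == rv:
            raise ValueError(f"edges contain a cycle (at edge ({u},{v}))")
        parent[ru] = rv


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth phase-coupling structure for one recording.

    Parameters
    ----------
    n_channels : int
        Number of channels (>= 2).
    tree_edges : tuple of (int, int)
        Spanning tree over channel indices along which phases are coupled.
    coupling_strength : float in [0, 1]
        0 = independent channels, 1 = maximal phase locking.
    phase_lag : float, radians
        Imposed phase difference along each (parent, child) edge. Must be
        away from 0 and pi: zero-lag relationships are produced only by
        the volume-conduction mixing stage, never by the source coupling.
    carrier_band : (float, float), Hz
        Frequency interval containing the oscillators' instantaneous
        frequencies.
    noise_sd : float
        Standard deviation of additive white sensor noise, in units of
        the (unit) carrier amplitude.
    freq_detune_sd : float, Hz
        Spread of per-channel intrinsic frequencies around the band
        centre.
    phase_noise : float, rad/sqrt(s)
        Intensity of the per-channel phase diffusion.
    coupling_rate : float, rad/s
        Coupling gain at ``coupling_strength`` = 1; locking requires it to
        exceed the intrinsic frequency detuning (in rad/s).
    amp_mod_depth : float
        Depth of the slow multiplicative amplitude modulation.
    """

    n_channels: int
    tree_edges: tuple[Edge, ...]
    coupling_strength: float = 0.9
    phase_lag: float = math.pi / 4
    carrier_band: tuple[float, float] = (13.0, 30.0)
    noise_sd: float = 0.3
    freq_detune_sd: float = 0.4
    phase_noise: float = 2.0
    coupling_rate: float = 25.0
    amp_mod_depth: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "tree_edges", tuple(tuple(e) for e in self.tree_edges))
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        _check_tree(self.n_channels, self.tree_edges)
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        lag = self.phase_lag % (2 * math.pi)
        if min(lag, abs(lag - math.pi), abs(lag - 2 * math.pi)) < 1e-9:
            raise ValueError(
                "phase_lag must not be 0 or pi: zero-lag coupling is expressed "
                "only through the mixing matrix"
            )
        low, high = self.carrier_band
        if not 0 < low < high:
            raise ValueError("carrier_band must satisfy 0 < low < high")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    Controls share the ``control_topology`` coupling tree (star-like);
    each patient gets a tree interpolated toward a path by
    ``patient_topology_shift + disability_topology_slope * disability/48``
    (clipped to [0, 1]). Control disability is 0; patient disability is
    drawn uniformly from the integer ``disability_range``.
    """

    control_topology: CouplingSpec
    n_patients: int = 21
    n_controls: int = 16
    patient_topology_shift: float = 0.35
    disability_topology_slope: float = 0.6
    disability_range: tuple[int, int] = (4, 40)
    mixing_spread: float = 1.0
    n_epochs: int = 4
    epoch_length: int = 2048
    fs: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        lo, hi = self.disability_range
        if not (0 < lo <= hi <= 48):
            raise ValueError("disability_range must lie within (0, 48]")
        if not 0.0 <= self.patient_topology_shift <= 1.0:
            raise ValueError("patient_topology_shift must lie in [0, 1]")
        if self.n_epochs <= 0 or self.epoch_length <= 0:
            raise ValueError("epoch settings must be positive")

    @classmethod
    def default(
        cls,
        n_channels: int = 61,
        control_shift: float = 0.1,
        **overrides,
    ) -> "CohortSpec":
        """Build a cohort spec with a star-like control coupling template."""
        coupling_overrides = {
            k: overrides.pop(k)
            for k in (
                "coupling_strength",
                "phase_lag",
                "carrier_band",
                "noise_sd",
                "freq_detune_sd",
                "phase_noise",
                "coupling_rate",
                "amp_mod_depth",
            )
            if k in overrides
        }
        template = CouplingSpec(
            n_channels=n_channels,
            tree_edges=make_interpolated_tree(n_channels, control_shift, seed=0),
            **coupling_overrides,
        )
        return cls(control_topology=template, **overrides)


@dataclass
class Subject:
    """One generated subject: recording plus clinical metadata."""

    subject_id: str
    group: str  # "patient" or "control"
    disability: int
    recording: Recording
    topology_shift: float
    tree_edges: tuple[Edge, ...]


def make_interpolated_tree(n_channels: int, shift: float, seed: int = 0) -> tuple[Edge, ...]:
    """Spanning tree interpolating between a star (shift=0) and a path (shift=1).

    Starting from a star centred on node 0, a fraction ``shift`` of the
    star's re-chainable leaves is detached and appended, in index order,
    to a chain growing from node 1. ``shift=1`` therefore yields the path
    0-1-2-...-(n-1). The construction is deterministic; ``seed`` is kept
    in the signature for interface symmetry with the stochastic
    generators.
    """
    if n_channels < 3:
        raise ValueError("interpolated tree needs n_channels >= 3")
    if not 0.0 <= shift <= 1.0:
        raise ValueError("shift must lie in [0, 1]")
    k = int(round(shift * (n_channels - 2)))  # leaves moved from hub to chain
    edges: list[Edge] = [(0, 1)]
    edges.extend((i, i + 1) for i in range(1, k + 1))
    edges.extend((0, j) for j in range(k + 2, n_channels))
    return tuple(edges)


def _orient_edges(n: int, edges: tuple[Edge, ...]) -> list[Edge]:
    """Orient tree edges as (parent, child) pairs by BFS from node 0."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    oriented: list[Edge] = []
    seen = [False] * n
    seen[0] = True
    queue = [0]
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                oriented.append((u, v))
                queue.append(v)
    return oriented


def _slow_modulation(rng: np.random.Generator, n: int, t: int, fs: float, tau: float = 0.5) -> np.ndarray:
    """Unit-variance slow (OU-filtered) noise, shape (n, t)."""
    a = math.exp(-1.0 / (tau * fs))
    white = rng.standard_normal((n, t))
    mod = _signal.lfilter([math.sqrt(1 - a * a)], [1.0, -a], white, axis=1)
    return mod


def generate_recording(
    spec: CouplingSpec,
    n_samples: int,
    fs: float,
    seed: int,
    labels: tuple[str, ...] | None = None,
) -> Recording:
    """Simulate one multichannel recording under ``spec``.

    Channel phases follow Euler-integrated Kuramoto-Sakaguchi dynamics on
    the coupling tree: each node's phase drifts at its intrinsic frequency
    (drawn inside ``carrier_band``), diffuses with intensity
    ``phase_noise``, and is pulled toward its tree neighbour's phase
    offset by ``phase_lag`` with gain
    ``coupling_strength * coupling_rate``. The emitted signal is a slowly
    amplitude-modulated cosine of the phase plus white sensor noise, so
    downstream phase-difference distributions are concentrated but not
    degenerate, like real narrowband EEG.
    """
    low, high = spec.carrier_band
    if not fs > 2 * high:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for carrier band upper edge {high} Hz"
        )
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    n = spec.n_channels

    # Complex coupling matrix: child c listens to parent p with lag +phase_lag,
    # parent listens back with -phase_lag (antisymmetric), so the locked state
    # satisfies phase(parent) - phase(child) = +phase_lag on every edge.
    # Each row is normalized by node degree, which keeps the per-sample pull
    # bounded by coupling_rate/fs regardless of hub size (Euler stability).
    deg = np.zeros(n)
    for u, v in spec.tree_edges:
        deg[u] += 1
        deg[v] += 1
    C = np.zeros((n, n), dtype=complex)
    for p, c in _orient_edges(n, spec.tree_edges):
        C[c, p] = np.exp(-1j * spec.phase_lag) / deg[c]
        C[p, c] = np.exp(+1j * spec.phase_lag) / deg[p]

    f0 = 0.5 * (low + high)
    freqs = np.clip(f0 + spec.freq_detune_sd * rng.standard_normal(n), low, high)
    omega = 2 * math.pi * freqs / fs  # rad per sample
    gain = spec.coupling_strength * spec.coupling_rate / fs
    sigma = spec.phase_noise / math.sqrt(fs)

    # Start at the stationary coupled state (no locking transient): each
    # child sits at parent - lag, perturbed in proportion to 1 - coupling.
    phi = np.empty(n)
    phi[0] = rng.uniform(-math.pi, math.pi)
    jitter = (1.0 - spec.coupling_strength) * math.pi
    for p, c in _orient_edges(n, spec.tree_edges):
        phi[c] = phi[p] - spec.phase_lag + jitter * rng.uniform(-1.0, 1.0)
    cos_phi = np.empty((n, n_samples))
    noise = rng.standard_normal((n, n_samples))
    for t in range(n_samples):
        cos_phi[:, t] = np.cos(phi)
        s = np.exp(1j * phi)
        pull = np.imag(np.conj(s) * (C @ s)) if gain > 0 else 0.0
        phi = phi + omega + gain * pull + sigma * noise[:, t]

    # Confine the carrier to its band: phase diffusion gives the bare cosine
    # Lorentzian tails that would otherwise leak coherent (tree-structured)
    # phase into the other analysis bands.
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    carrier = _signal.sosfiltfilt(sos, cos_phi, axis=-1)

    amp = 1.0 + spec.amp_mod_depth * _slow_modulation(rng, n, n_samples, fs)
    amp = np.clip(amp, 0.1, None)
    data = amp * carrier + spec.noise_sd * rng.standard_normal((n, n_samples))
    if labels is None:
        labels = default_labels(n)
    return Recording(data=data, labels=labels, fs=fs)


def mixing_matrix(n_channels: int, spread: float) -> np.ndarray:
    """Row-normalized zero-lag leakage matrix with exponential falloff.

    Entry (i, j) is proportional to exp(-|i-j| / spread); ``spread <= 0``
    yields the identity (no leakage). Rows sum to 1 and the diagonal
    dominates, a simple monotone surrogate for volume conduction that
    needs no electrode geometry.
    """
    if spread <= 0:
        return np.eye(n_channels)
    idx = np.arange(n_channels)
    m = np.exp(-np.abs(idx[:, None] - idx[None, :]) / spread)
    return m / m.sum(axis=1, keepdims=True)


def apply_volume_conduction(rec: Recording, mixing: np.ndarray) -> Recording:
    """Instantaneously mix channels: out[:, t] = mixing @ in[:, t].

    Purely spatial (same-time) mixing with nonnegative gains and a
    dominant diagonal — the kind of zero-lag field spread that phase-lag
    based connectivity is designed to discount.
    """
    mixing = np.asarray(mixing, dtype=float)
    n = rec.n_channels
    if mixing.shape != (n, n):
        raise ValueError(f"mixing must be {n}x{n}, got {mixing.shape}")
    if np.any(mixing < 0):
        raise ValueError("mixing gains must be nonnegative")
    off = mixing - np.diag(np.diag(mixing))
    if np.any(np.diag(mixing) < off.max(axis=1)):
        raise ValueError("mixing matrix must have a dominant diagonal")
    return replace(rec, data=mixing @ rec.data)


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate a full two-group cohort, reproducible from ``spec.seed``.

    Patient ``i`` receives topology shift
    ``clip(patient_topology_shift + disability_topology_slope * d_i / 48, 0, 1)``
    where ``d_i`` is the subject's disability score; controls keep the
    template tree. Every recording is long enough for the configured
    epoch grid and passes through the volume-conduction mixing stage.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_patients + spec.n_controls
    children = ss.spawn(n_total + 1)
    meta_rng = np.random.default_rng(children[0])
    lo, hi = spec.disability_range
    disabilities = meta_rng.integers(lo, hi + 1, size=spec.n_patients)

    n_samples = spec.n_epochs * spec.epoch_length
    template = spec.control_topology
    mixing = mixing_matrix(template.n_channels, spec.mixing_spread)

    subjects: list[Subject] = []
    for i in range(n_total):
        child_seed = int(children[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        if i < spec.n_patients:
            group = "patient"
            subject_id = f"P{i + 1:02d}"
            disability = int(disabilities[i])
            shift = float(
                np.clip(
                    spec.patient_topology_shift
                    + spec.disability_topology_slope * disability / 48.0,
                    0.0,
                    1.0,
                )
            )
            tree = make_interpolated_tree(template.n_channels, shift, seed=child_seed)
            coupling = replace(template, tree_edges=tree)
        else:
            group = "control"
            subject_id = f"C{i - spec.n_patients + 1:02d}"
            disability = 0
            shift = float("nan")
            coupling = template
        rec = generate_recording(coupling, n_samples, spec.fs, seed=child_seed)
        rec = apply_volume_conduction(rec, mixing)
        subjects.append(
            Subject(
                subject_id=subject_id,
                group=group,
                disability=disability,
                recording=rec,
                topology_shift=shift,
                tree_edges=coupling.tree_edges,
            )
        )
    return subjects
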