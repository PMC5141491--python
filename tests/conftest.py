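"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest

from mstnet import BANDS, CouplingSpec, EpochSet, Recording


def prufer_trees(n: int):
    """All n^(n-2) labelled trees on n nodes, as frozensets of sorted edges.

    Independent enumeration oracle (Cayley's formula via Prüfer sequences).
    """
    for seq in product(range(n), repeat=n - 2):
        g = nx.from_prufer_sequence(list(seq))
        yield frozenset((min(u, v), max(u, v)) for u, v in g.edges)


def tree_weight(edges, weight_matrix: np.ndarray) -> float:
    return float(sum(weight_matrix[u, v] for u, v in edges))


def exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all group assignments.

    Brute-force oracle: the U statistic of the first group is computed for
    every C(n1+n2, n1) split of the pooled sample; the two-sided p doubles
    the smaller tail (the null distribution of U is symmetric).
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n = len(pooled)

    def u_of(idx: tuple[int, ...]) -> int:
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return int(sum((x > y) + 0.5 * (x == y) for x in grp for y in rest))

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(idx) for idx in combinations(range(n), n1)]
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return float(min(1.0, 2 * min(lower, upper)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def beta() -> "BandDefinition":
    return BANDS["beta"]


def make_recording(data: np.ndarray, fs: float = 256.0, **kw) -> Recording:
    labels = tuple(f"CH{i + 1:02d}" for i in range(data.shape[0]))
    return Recording(data=np.asarray(data, dtype=float), labels=labels, fs=fs, **kw)


def phases_to_epochset(phases: np.ndarray, fs: float = 256.0) -> EpochSet:
    """Wrap cosines of given phases (channels x samples) as a 1-epoch set."""
    data = np.cos(phases)[None, :, :]
    labels = tuple(f"CH{i + 1:02d}" for i in range(phases.shape[0]))
    return EpochSet(data=data, labels=labels, fs=fs)


@pytest.fixture
def coupled_pair_spec() -> CouplingSpec:
    return CouplingSpec(
        n_channels=2,
        tree_edges=((0, 1),),
        coupling_strength=0.95,
        phase_lag=np.pi / 2,
        noise_sd=0.0,
    )
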