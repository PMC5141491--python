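"""Synthetic-cohort generator: trees, recordings, mixing, cohorts."""

import numpy as np
import pytest

from mstnet import (
    BANDS,
    CohortSpec,
    CouplingSpec,
    SpanningTree,
    apply_volume_conduction,
    bandpass_filter,
    extract_epochs,
    generate_cohort,
    generate_recording,
    leaf_fraction,
    make_interpolated_tree,
    mixing_matrix,
    pli_matrix,
)

from conftest import make_recording


class TestInterpolatedTree:
    def test_shift_zero_is_star(self):
        assert set(make_interpolated_tree(5, 0.0)) == {(0, 1), (0, 2), (0, 3), (0, 4)}

    def test_shift_one_is_path(self):
        assert set(make_interpolated_tree(5, 1.0)) == {(0, 1), (1, 2), (2, 3), (3, 4)}

    def test_intermediate_leaf_fraction_strictly_between_extremes(self):
        edges = make_interpolated_tree(58, 0.5, seed=7)
        lf = leaf_fraction(SpanningTree(n_nodes=58, edges=frozenset(edges)))
        assert 2 / 58 < lf < 57 / 58

    @pytest.mark.parametrize("shift", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    def test_always_a_valid_spanning_tree(self, shift):
        # SpanningTree validates connectivity/acyclicity on construction
        edges = make_interpolated_tree(12, shift)
        SpanningTree(n_nodes=12, edges=frozenset(edges))

    def test_leaf_fraction_and_diameter_monotone_along_interpolation(self):
        from mstnet import diameter

        shifts = np.linspace(0, 1, 11)
        trees = [
            SpanningTree(n_nodes=20, edges=frozenset(make_interpolated_tree(20, s)))
            for s in shifts
        ]
        lfs = [leaf_fraction(t) for t in trees]
        diams = [diameter(t) for t in trees]
        assert all(a >= b for a, b in zip(lfs, lfs[1:]))
        assert all(a <= b for a, b in zip(diams, diams[1:]))

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="n_channels"):
            make_interpolated_tree(2, 0.5)


class TestCouplingSpecValidation:
    def test_zero_phase_lag_rejected(self):
        with pytest.raises(ValueError, match="phase_lag"):
            CouplingSpec(n_channels=2, tree_edges=((0, 1),), phase_lag=0.0)

    def test_pi_phase_lag_rejected(self):
        with pytest.raises(ValueError, match="phase_lag"):
            CouplingSpec(n_channels=2, tree_edges=((0, 1),), phase_lag=np.pi)

    def test_cyclic_edges_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            CouplingSpec(n_channels=4, tree_edges=((0, 1), (1, 2), (0, 2)))

    def test_wrong_edge_count_rejected(self):
        with pytest.raises(ValueError, match="edges"):
            CouplingSpec(n_channels=4, tree_edges=((0, 1), (1, 2)))


class TestGenerateRecording:
    def test_deterministic_under_seed(self, coupled_pair_spec):
        a = generate_recording(coupled_pair_spec, 512, 256.0, seed=5)
        b = generate_recording(coupled_pair_spec, 512, 256.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_nyquist_violation_raises(self, coupled_pair_spec):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_recording(coupled_pair_spec, 512, 50.0, seed=0)

    def test_coupled_pair_has_unit_pli(self, coupled_pair_spec):
        """A noiseless pair locked at lag pi/2 gives PLI exactly 1."""
        rec = generate_recording(coupled_pair_spec, 2048, 256.0, seed=1)
        filt = bandpass_filter(extract_epochs(rec, 1, 2048), BANDS["beta"])
        assert pli_matrix(filt, edge_trim=128)[0].weights[0, 1] == 1.0

    def test_uncoupled_pair_pli_at_null_level(self):
        spec = CouplingSpec(
            n_channels=2, tree_edges=((0, 1),), coupling_strength=0.0, noise_sd=1.0
        )
        vals = []
        for seed in range(5):
            rec = generate_recording(spec, 2048, 256.0, seed=seed)
            filt = bandpass_filter(extract_epochs(rec, 1, 2048), BANDS["beta"])
            vals.append(pli_matrix(filt)[0].weights[0, 1])
        assert np.mean(vals) < 0.2

    def test_star_topology_recovered_from_mean_pli(self):
        """Strong star coupling: the MST recovers >= 80% of the true edges."""
        from mstnet import ConnectivityMatrix, build_mst

        edges = make_interpolated_tree(58, 0.0)
        spec = CouplingSpec(
            n_channels=58, tree_edges=edges, coupling_strength=0.9, noise_sd=0.1
        )
        rec = generate_recording(spec, 4 * 2048, 256.0, seed=3)
        filt = bandpass_filter(extract_epochs(rec, 4, 2048), BANDS["beta"])
        mats = pli_matrix(filt)
        mean_w = np.mean([m.weights for m in mats], axis=0)
        tree = build_mst(ConnectivityMatrix(weights=mean_w, labels=mats[0].labels))
        assert len(tree.edges & frozenset(edges)) >= 0.8 * 57

    def test_amplitude_finite(self, coupled_pair_spec):
        rec = generate_recording(coupled_pair_spec, 1024, 256.0, seed=0)
        assert np.all(np.isfinite(rec.data))


class TestVolumeConduction:
    def test_identity_mixing_is_identity(self, rng):
        rec = make_recording(rng.standard_normal((4, 64)))
        out = apply_volume_conduction(rec, np.eye(4))
        np.testing.assert_array_equal(out.data, rec.data)

    def test_dimension_mismatch_raises(self, rng):
        rec = make_recording(rng.standard_normal((4, 64)))
        with pytest.raises(ValueError, match="4x4"):
            apply_volume_conduction(rec, np.eye(3))

    def test_negative_gain_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 8)))
        with pytest.raises(ValueError, match="nonnegative"):
            apply_volume_conduction(rec, np.array([[1.0, -0.1], [0.0, 1.0]]))

    def test_zero_row_gives_flat_channel(self):
        rec = make_recording(np.ones((2, 16)))
        mix = np.array([[0.0, 0.0], [0.0, 1.0]])
        out = apply_volume_conduction(rec, mix)
        np.testing.assert_array_equal(out.data[0], 0.0)

    def test_default_mixing_rows_normalized_and_diagonal_dominant(self):
        m = mixing_matrix(10, spread=1.0)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        assert np.all(np.diag(m) >= (m - np.diag(np.diag(m))).max(axis=1))
        np.testing.assert_array_equal(mixing_matrix(5, 0.0), np.eye(5))


@pytest.fixture(scope="module")
def small_spec():
    return CohortSpec.default(
        n_channels=8,
        n_patients=3,
        n_controls=2,
        n_epochs=2,
        epoch_length=256,
        seed=42,
    )


class TestGenerateCohort:
    def test_counts_groups_disability(self, small_spec):
        subjects = generate_cohort(small_spec)
        patients = [s for s in subjects if s.group == "patient"]
        controls = [s for s in subjects if s.group == "control"]
        assert (len(patients), len(controls)) == (3, 2)
        assert all(0 < s.disability <= 48 for s in patients)
        assert all(s.disability == 0 for s in controls)

    def test_recordings_sized_for_epoch_grid(self, small_spec):
        subjects = generate_cohort(small_spec)
        assert all(s.recording.n_samples >= 2 * 256 for s in subjects)

    def test_bit_identical_under_same_spec(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert sa.disability == sb.disability
            np.testing.assert_array_equal(sa.recording.data, sb.recording.data)

    def test_patient_shift_increases_with_disability(self, small_spec):
        subjects = generate_cohort(small_spec)
        patients = sorted(
            (s for s in subjects if s.group == "patient"), key=lambda s: s.disability
        )
        shifts = [s.topology_shift for s in patients]
        assert all(a <= b for a, b in zip(shifts, shifts[1:]))
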