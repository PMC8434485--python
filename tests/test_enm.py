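"""Elastic models: Hessian/Kirchhoff construction, spectra, overlap, reduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allodyn as ad
from allodyn.enm import rigid_motion_basis, substructure

from conftest import line_structure, point_structure


class TestBuildModel:
    def test_single_spring_hessian(self):
        """Two nodes on the x-axis at distance 1: analytic 3×3 block."""
        s = line_structure([0.0, 1.0])
        H = ad.ANM(s, cutoff=15).matrix
        block = H[0:3, 3:6]
        np.testing.assert_allclose(block, -np.diag([1.0, 0.0, 0.0]), atol=1e-12)
        np.testing.assert_allclose(H[0:3, 0:3], np.diag([1.0, 0.0, 0.0]), atol=1e-12)

    def test_path_graph_kirchhoff(self):
        s = line_structure([0.0, 8.0, 16.0])
        K = ad.GNM(s, cutoff=10).matrix
        np.testing.assert_array_equal(K, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_beyond_cutoff_zero_matrix(self):
        s = line_structure([0.0, 20.0])
        assert not ad.ANM(s, cutoff=15).matrix.any()
        assert not ad.GNM(s, cutoff=10).matrix.any()

    def test_boundary_inclusive(self):
        s = line_structure([0.0, 10.0])
        assert ad.GNM(s, cutoff=10).matrix[0, 1] == -1.0

    def test_gamma_scales_matrix(self, globule20):
        H1 = ad.ANM(globule20, gamma=1.0).matrix
        H2 = ad.ANM(globule20, gamma=2.5).matrix
        np.testing.assert_allclose(H2, 2.5 * H1)

    def test_gnm_is_graph_laplacian(self, globule20):
        K = ad.GNM(globule20).matrix
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-12)
        offdiag = K[~np.eye(len(K), dtype=bool)]
        assert set(np.unique(offdiag)) <= {0.0, -1.0}
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-10


class TestDecompose:
    def test_anm_mode_count_law(self):
        s = ad.make_structure(ad.SynthSpec(10, "globule", seed=4))
        modes = ad.ANM(s).fit()
        assert modes.n_zero == 6
        assert len(modes.nonzero_eigenvalues) == 24

    def test_gnm_mode_count_law(self, globule20):
        assert ad.GNM(globule20).fit().n_zero == 1

    def test_disconnected_gnm_counts_components(self, caplog):
        import logging

        s = line_structure([0, 4, 8, 100, 104, 108])
        with caplog.at_level(logging.WARNING, logger="allodyn.enm"):
            modes = ad.GNM(s, cutoff=10).fit()
        assert modes.n_zero == 2
        assert any("near-zero" in r.message for r in caplog.records)

    def test_translation_in_null_space(self, anm20):
        t = np.tile([1.0, -2.0, 0.5], anm20.structure.n_residues)
        assert np.linalg.norm(anm20.model.matrix @ t) < 1e-8

    def test_eigenvalues_ascending_orthonormal(self, anm20):
        w = anm20.eigenvalues
        assert (np.diff(w) >= -1e-12).all()
        V = anm20.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(len(w)), atol=1e-9)


class TestModeFluctuations:
    def test_profile_sums_to_one(self, globule20):
        modes = ad.GNM(globule20).fit()
        for k in (1, 2, 5):
            assert ad.mode_fluctuations(modes, k).sum() == pytest.approx(1.0, abs=1e-12)

    def test_path_graph_mode1_symmetric(self):
        """Slowest Laplacian mode of a path graph is symmetric about the middle."""
        s = line_structure(np.arange(7) * 8.0)
        prof = ad.GNM(s, cutoff=10).fit().mode_fluctuations(1)
        np.testing.assert_allclose(prof, prof[::-1], atol=1e-10)

    def test_zero_mode_index_rejected(self, globule20):
        modes = ad.GNM(globule20).fit()
        with pytest.raises(IndexError):
            ad.mode_fluctuations(modes, 0)

    def test_msf_permutation_equivariant(self, globule20):
        rng = np.random.default_rng(0)
        perm = rng.permutation(globule20.n_residues)
        msf = ad.GNM(globule20).fit().msf()
        permuted = point_structure(globule20.ca_coords[perm])
        msf_p = ad.GNM(permuted).fit().msf()
        np.testing.assert_allclose(msf_p, msf[perm], atol=1e-10)


class TestCumulativeOverlap:
    def test_identity(self, anm20):
        res = ad.cumulative_overlap(anm20, anm20, k=10)
        assert res.overlap == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.diag(res.pair_matrix), 1.0, atol=1e-10)

    def test_full_space_remix_completeness(self, anm20):
        """Any orthonormal re-mixing of the complete nonzero basis overlaps at 1."""
        V = anm20.modes()
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((V.shape[1],) * 2))
        res = ad.cumulative_overlap(V, V @ Q)
        assert res.overlap == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_modes(self):
        u = np.array([[1.0], [0.0], [0.0]])
        v = np.array([[0.0], [1.0], [0.0]])
        assert ad.cumulative_overlap(u, v).overlap == 0.0

    def test_symmetric_in_arguments(self, anm20):
        A = anm20.modes(6)
        rng = np.random.default_rng(2)
        B, _ = np.linalg.qr(rng.standard_normal((A.shape[0], 6)))
        ab = ad.cumulative_overlap(A, B).cumulative
        ba = ad.cumulative_overlap(B, A).cumulative
        np.testing.assert_allclose(ab, ba, atol=1e-12)

    def test_dimension_mismatch(self, anm20):
        with pytest.raises(ValueError):
            ad.cumulative_overlap(anm20.modes(3), np.eye(5)[:, :3])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2**31 - 1))
    def test_bounded_in_unit_interval(self, k, seed):
        rng = np.random.default_rng(seed)
        A, _ = np.linalg.qr(rng.standard_normal((3 * k, k)))
        B, _ = np.linalg.qr(rng.standard_normal((3 * k, k)))
        res = ad.cumulative_overlap(A, B)
        assert (res.pair_matrix >= 0).all() and (res.pair_matrix <= 1 + 1e-12).all()
        assert (res.cumulative >= 0).all() and (res.cumulative <= 1 + 1e-9).all()


def _internal_block(modes, indices):
    """Full-model covariance block projected on the subsystem's internal subspace."""
    dof = np.ravel(3 * np.asarray(indices)[:, None] + np.arange(3))
    C = modes.covariance()[np.ix_(dof, dof)]
    Q = rigid_motion_basis(modes.structure.ca_coords[indices])
    P = np.eye(len(dof)) - Q @ Q.T
    return P @ C @ P


class TestSubsystemReduction:
    def test_uncoupled_environment_leaves_hessian(self):
        """No cross-contacts: the Schur complement is the plain subsystem block."""
        a = ad.make_structure(ad.SynthSpec(10, "globule", seed=1))
        b = ad.make_structure(ad.SynthSpec(8, "globule", seed=2))
        coords = np.vstack([a.ca_coords, b.ca_coords + 100.0])
        s = point_structure(coords, ["A"] * 10 + ["B"] * 8)
        model = ad.ANM(s)
        sub = ad.ResidueSelection(frozenset(range(10)), "subsystem")
        red = ad.reduce_to_subsystem(model, sub)
        np.testing.assert_array_equal(red.matrix, model.matrix[:30, :30])
        # and the standalone subsystem spectrum is recovered
        solo = ad.ANM(substructure(s, list(range(10)))).fit()
        np.testing.assert_allclose(
            red.fit().nonzero_eigenvalues, solo.nonzero_eigenvalues, atol=1e-10
        )

    def test_three_node_chain_static_condensation(self):
        """Eliminating the middle node matches a hand-coded dense solve."""
        s = line_structure([0.0, 1.0, 2.0])
        model = ad.ANM(s, cutoff=1.5)
        sub = ad.ResidueSelection(frozenset([0, 2]), "ends")
        red = ad.reduce_to_subsystem(model, sub)
        H = model.matrix
        keep = np.r_[0:3, 6:9]
        mid = np.r_[3:6]
        Hee = H[np.ix_(mid, mid)]
        expect = H[np.ix_(keep, keep)] - H[np.ix_(keep, mid)] @ np.linalg.pinv(
            Hee
        ) @ H[np.ix_(mid, keep)]
        np.testing.assert_allclose(red.matrix, expect, atol=1e-12)

    def test_reduced_covariance_matches_full_internal_block(self, complex24):
        model = ad.ANM(complex24)
        sl = complex24.chain_slices()
        idx = list(range(sl["A"].start, sl["A"].stop))
        sub = ad.ResidueSelection(frozenset(idx), "subsystem")
        red = ad.reduce_to_subsystem(model, sub).fit()
        target = _internal_block(model.fit(), idx)
        assert np.abs(red.covariance() - target).max() < 1e-8

    def test_full_subsystem_rejected(self, globule20):
        model = ad.ANM(globule20)
        sub = ad.ResidueSelection(frozenset(range(20)), "all")
        with pytest.raises(ValueError):
            ad.reduce_to_subsystem(model, sub)
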