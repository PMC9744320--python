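import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dtiglyph as dg
from dtiglyph.tensor import design_matrix
from conftest import eigenfield_from_triples


def scalar_oracle(L1, L2, L3):
    """Independent scalar implementation of FA/MD/RD (pure python)."""
    sumsq = L1 * L1 + L2 * L2 + L3 * L3
    if sumsq == 0:
        fa = float("nan")
    else:
        fa = math.sqrt(((L1 - L2) ** 2 + (L2 - L3) ** 2 + (L1 - L3) ** 2) / (2 * sumsq))
    return fa, (L1 + L2 + L3) / 3.0, (L2 + L3) / 2.0


SIX_DIRS = np.array(
    [(1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)],
    dtype=float,
) / np.sqrt(2)


def _dwi_from_tensor(D, bvals, bvecs, S0=1000.0):
    adc = np.einsum("ni,ij,nj->n", bvecs, D, bvecs)
    signal = (S0 * np.exp(-bvals * adc)).reshape(1, 1, 1, -1)
    return dg.DWIVolume(signal, bvals, bvecs, np.eye(4))


class TestFit:
    def test_noiseless_phantom_recovered_exactly(self):
        """OLS on noiseless forward-model data inverts the diagonal tensor."""
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        dirs = dg.spread_directions(64)
        bvals = np.concatenate([[0.0], np.full(64, 1000.0)])
        bvecs = np.vstack([np.zeros(3), dirs])
        tf = dg.fit_tensor(_dwi_from_tensor(D, bvals, bvecs))
        np.testing.assert_allclose(tf.D[0, 0, 0, :3], np.diag(D), rtol=1e-9)
        np.testing.assert_allclose(tf.D[0, 0, 0, 3:], 0.0, atol=1e-12)

    def test_determined_six_direction_solve_matches_inversion_oracle(self):
        """6 directions + 1 baseline is a square system; the fit must agree
        with a direct 7x7 matrix inversion done independently."""
        rng = np.random.default_rng(11)
        A = rng.normal(size=(3, 3))
        D = A @ A.T * 1e-4 + np.eye(3) * 5e-4  # SPD
        bvals = np.concatenate([[0.0], np.full(6, 1000.0)])
        bvecs = np.vstack([np.zeros(3), SIX_DIRS])
        dwi = _dwi_from_tensor(D, bvals, bvecs)

        X = design_matrix(bvals, bvecs)
        oracle = np.linalg.solve(X, np.log(dwi.signal[0, 0, 0]))
        tf = dg.fit_tensor(dwi)
        np.testing.assert_allclose(tf.D[0, 0, 0], oracle[1:], rtol=1e-10)
        np.testing.assert_allclose(tf.S0[0, 0, 0], math.exp(oracle[0]), rtol=1e-10)

    def test_flat_signal_gives_zero_tensor(self):
        bvals = np.concatenate([[0.0], np.full(8, 1000.0)])
        bvecs = np.vstack([np.zeros(3), dg.spread_directions(8)])
        signal = np.full((2, 2, 1, 9), 500.0)
        tf = dg.fit_tensor(dg.DWIVolume(signal, bvals, bvecs, np.eye(4)))
        np.testing.assert_allclose(tf.D, 0.0, atol=1e-15)
        np.testing.assert_allclose(tf.S0, 500.0)

    def test_too_few_volumes_and_no_baseline_raise(self):
        bvecs = np.vstack([np.zeros(3), dg.spread_directions(5)])
        dwi = dg.DWIVolume(np.ones((2, 2, 2, 6)),
                           np.concatenate([[0.0], np.full(5, 1000.0)]), bvecs, np.eye(4))
        with pytest.raises(ValueError, match="at least 7"):
            dg.fit_tensor(dwi)
        dwi = dg.DWIVolume(np.ones((2, 2, 2, 8)), np.full(8, 1000.0),
                           dg.spread_directions(8), np.eye(4))
        with pytest.raises(ValueError, match="baseline"):
            dg.fit_tensor(dwi)

    def test_coplanar_gradients_raise_with_condition_number(self):
        theta = np.linspace(0, np.pi, 8, endpoint=False)
        bvecs = np.vstack([np.zeros(3),
                           np.column_stack([np.cos(theta), np.sin(theta), np.zeros(8)])])
        bvals = np.concatenate([[0.0], np.full(8, 1000.0)])
        dwi = dg.DWIVolume(np.ones((1, 1, 1, 9)), bvals, bvecs, np.eye(4))
        with pytest.raises(ValueError, match="condition number"):
            dg.fit_tensor(dwi)

    def test_nonpositive_signal_uses_positive_subset(self):
        D = np.diag([1.5e-3, 4e-4, 4e-4])
        dirs = dg.spread_directions(16)
        bvals = np.concatenate([[0.0], np.full(16, 1000.0)])
        bvecs = np.vstack([np.zeros(3), dirs])
        dwi = _dwi_from_tensor(D, bvals, bvecs)
        sig = dwi.signal.copy()
        sig[0, 0, 0, 5] = 0.0  # one corrupted measurement
        tf = dg.fit_tensor(dg.DWIVolume(sig, bvals, bvecs, np.eye(4)))
        np.testing.assert_allclose(tf.D[0, 0, 0, :3], np.diag(D), rtol=1e-9)


class TestEigendecompose:
    def test_diagonal_tensor(self):
        tf = dg.TensorField(
            D=np.array([3e-3, 2e-3, 1e-3, 0, 0, 0]).reshape(1, 1, 1, 6),
            S0=np.ones((1, 1, 1)), affine=np.eye(4))
        ef = dg.eigendecompose(tf)
        np.testing.assert_allclose(
            [ef.L1[0, 0, 0], ef.L2[0, 0, 0], ef.L3[0, 0, 0]], [3e-3, 2e-3, 1e-3])
        assert abs(ef.V1[0, 0, 0] @ (1, 0, 0)) == pytest.approx(1.0)

    def test_isotropic_tensor_any_orthonormal_basis(self):
        tf = dg.TensorField(
            D=np.array([1e-3, 1e-3, 1e-3, 0, 0, 0]).reshape(1, 1, 1, 6),
            S0=np.ones((1, 1, 1)), affine=np.eye(4))
        ef = dg.eigendecompose(tf)
        assert ef.L1[0, 0, 0] == pytest.approx(ef.L3[0, 0, 0])
        V = np.stack([ef.V1[0, 0, 0], ef.V2[0, 0, 0], ef.V3[0, 0, 0]])
        np.testing.assert_allclose(V @ V.T, np.eye(3), atol=1e-12)

    def test_reconstruction_on_random_symmetric_tensors(self):
        rng = np.random.default_rng(3)
        M = rng.normal(scale=1e-3, size=(50, 3, 3))
        M = (M + M.transpose(0, 2, 1)) / 2
        tf = dg.TensorField(
            D=np.stack([M[:, 0, 0], M[:, 1, 1], M[:, 2, 2],
                        M[:, 0, 1], M[:, 0, 2], M[:, 1, 2]], axis=-1).reshape(50, 1, 1, 6),
            S0=np.ones((50, 1, 1)), affine=np.eye(4))
        ef = dg.eigendecompose(tf)
        L = ef.eigenvalues()[:, 0, 0]
        V = np.stack([ef.V1, ef.V2, ef.V3], axis=-1)[:, 0, 0]
        recon = np.einsum("nik,nk,njk->nij", V, L, V)
        assert np.abs(recon - M).max() <= 1e-12 * np.abs(M).max()
        assert (np.diff(L, axis=-1) <= 1e-18).all()  # descending

    def test_eigenvectors_orthonormal(self, healthy_phantom):
        ef, _, _ = healthy_phantom
        for a, b in [("V1", "V2"), ("V1", "V3"), ("V2", "V3")]:
            dots = np.abs((getattr(ef, a) * getattr(ef, b)).sum(-1))
            assert dots.max() < 1e-6
        for name in ("V1", "V2", "V3"):
            norms = np.linalg.norm(getattr(ef, name), axis=-1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-6)


class TestClamp:
    @pytest.mark.parametrize("triple, expected", [
        ((2e-3, 1e-3, -0.5e-3), (2e-3, 1e-3, 0.0)),
        ((-1e-3, -2e-3, -3e-3), (0.0, 0.0, 0.0)),
    ])
    def test_negative_values_zeroed(self, triple, expected):
        ef = eigenfield_from_triples([triple], clamped=False)
        out = dg.clamp_negative(ef)
        assert (out.L1[0, 0, 0], out.L2[0, 0, 0], out.L3[0, 0, 0]) == expected
        assert out.clamped

    @given(st.lists(st.tuples(*[st.floats(-5e-3, 5e-3)] * 3), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_never_grows_magnitude(self, triples):
        triples = [tuple(sorted(t, reverse=True)) for t in triples]
        ef = eigenfield_from_triples(triples, clamped=False)
        once = dg.clamp_negative(ef)
        twice = dg.clamp_negative(once)
        for name in ("L1", "L2", "L3"):
            np.testing.assert_array_equal(getattr(once, name), getattr(twice, name))
            assert (np.abs(getattr(once, name)) <= np.abs(getattr(ef, name)) + 0).all()
        assert min(once.L3.min(), once.L2.min(), once.L1.min()) >= 0


class TestScalars:
    def test_matches_independent_oracle_on_random_triples(self):
        rng = np.random.default_rng(0)
        triples = -np.sort(-rng.uniform(0, 3e-3, size=(10_000, 3)), axis=1)
        sc = dg.compute_scalars(eigenfield_from_triples(triples))
        for i in [0, 1, 17, 4999, 9999]:
            fa, md, rd = scalar_oracle(*triples[i])
            assert sc.FA.ravel()[i] == pytest.approx(fa, rel=1e-12)
            assert sc.MD.ravel()[i] == pytest.approx(md, rel=1e-12)
            assert sc.RD.ravel()[i] == pytest.approx(rd, rel=1e-12)

    @pytest.mark.parametrize("triple, fa, md, rd", [
        ((1e-3, 1e-3, 1e-3), 0.0, 1e-3, 1e-3),
        ((1e-3, 0.0, 0.0), 1.0, 1e-3 / 3, 0.0),
        ((3e-3, 2e-3, 1e-3), 0.4629100498862757, 2e-3, 1.5e-3),
    ])
    def test_reference_triples(self, triple, fa, md, rd):
        sc = dg.compute_scalars(eigenfield_from_triples([triple]))
        assert sc.FA[0, 0, 0] == pytest.approx(fa, rel=1e-12, abs=1e-15)
        assert sc.MD[0, 0, 0] == pytest.approx(md, rel=1e-12)
        assert sc.RD[0, 0, 0] == pytest.approx(rd, rel=1e-12, abs=1e-15)

    def test_fa_nan_at_zero_tensor_and_unclamped_rejected(self):
        sc = dg.compute_scalars(eigenfield_from_triples([(0.0, 0.0, 0.0)]))
        assert np.isnan(sc.FA[0, 0, 0])
        with pytest.raises(ValueError, match="clamp"):
            dg.compute_scalars(eigenfield_from_triples([(1e-3, 1e-3, 1e-3)], clamped=False))

    @given(st.floats(1e-6, 1e3), st.tuples(*[st.floats(0, 3e-3)] * 3))
    @settings(deadline=None, max_examples=100)
    def test_fa_scale_invariance(self, c, triple):
        triple = tuple(sorted(triple, reverse=True))
        fa1 = dg.compute_scalars(eigenfield_from_triples([triple])).FA[0, 0, 0]
        scaled = tuple(c * x for x in triple)
        fa2 = dg.compute_scalars(eigenfield_from_triples([scaled])).FA[0, 0, 0]
        if np.isnan(fa1):
            assert np.isnan(fa2)
        else:
            assert fa2 == pytest.approx(fa1, rel=1e-9)


class TestQC:
    def test_counting_on_constructed_field(self):
        """1000 voxels with 9/65/90 negative L1/L2/L3 -> 0.9/6.5/9.0 percent."""
        rng = np.random.default_rng(5)
        L = rng.uniform(1e-4, 3e-3, size=(1000, 3))
        L = -np.sort(-L, axis=1)
        L[:9, 0] = -1e-4
        L[:65, 1] = -2e-4
        L[:90, 2] = -3e-4
        L = -np.sort(-L, axis=1)  # keep descending after the sign flips
        qc = dg.qc_negative_fraction(eigenfield_from_triples(L, clamped=False))
        assert qc.negative_fraction_L1 == pytest.approx(0.9)
        assert qc.negative_fraction_L2 == pytest.approx(6.5)
        assert qc.negative_fraction_L3 == pytest.approx(9.0)

    def test_three_voxel_example_and_all_positive(self):
        qc = dg.qc_negative_fraction(eigenfield_from_triples(
            [(2e-3, 1e-3, 5e-4), (2e-3, -1e-4, -2e-4), (1e-3, 8e-4, 2e-4)], clamped=False))
        assert qc.negative_fraction_L1 == 0.0
        assert qc.negative_fraction_L2 == pytest.approx(100 / 3)
        qc2 = dg.qc_negative_fraction(eigenfield_from_triples(
            [(2e-3, 1e-3, 5e-4)], clamped=False))
        assert (qc2.negative_fraction_L1, qc2.negative_fraction_L2,
                qc2.negative_fraction_L3) == (0.0, 0.0, 0.0)

    def test_clamped_input_rejected(self):
        with pytest.raises(ValueError, match="pre-clamp"):
            dg.qc_negative_fraction(eigenfield_from_triples([(1e-3, 1e-3, 1e-3)]))
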