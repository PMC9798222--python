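"""Forward models: algebraic identities, invariances, quadrature oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cortecs as c
from cortecs.acquisition import B_LAMBDA_SCALE


def delta_spectrum(grid, index):
    w = np.zeros(grid.shape)
    w[index] = 1.0
    return c.CDTDSpectrum(grid, w)


@pytest.fixture(scope="module")
def grid3():
    return c.SpectralGrid.logspaced(3, 8)


@pytest.fixture(scope="module")
def spec3(grid3):
    rng = np.random.default_rng(0)
    w = rng.random(grid3.shape)
    return c.CDTDSpectrum(grid3, w / w.sum())


class TestBtensor3D:
    def test_zero_btensor_returns_total_mass(self, spec3):
        assert c.signal_btensor_3d(spec3, np.eye(3), np.zeros((3, 3))) == pytest.approx(
            spec3.mass, rel=1e-12
        )

    def test_rank_one_equals_sde(self, spec3):
        rng = np.random.default_rng(1)
        F = Rotation.random(random_state=2).as_matrix()
        for _ in range(5):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            b = float(rng.uniform(100, 10000))
            s_bt = c.signal_btensor_3d(spec3, F, c.btensor_from_sde(b, g))
            s_sde = c.signal_sde_3d(spec3, F, b, g)
            assert s_bt == pytest.approx(s_sde, rel=1e-12)

    def test_isotropic_spectrum_rotation_invariant(self, grid3):
        # weights symmetric under axis permutation + spherical b-tensor
        w = np.fromfunction(lambda i, j, k: 1.0 / (1 + i + j + k), grid3.shape)
        w = (w + w.transpose(1, 2, 0) + w.transpose(2, 0, 1)
             + w.transpose(0, 2, 1) + w.transpose(1, 0, 2) + w.transpose(2, 1, 0))
        spec = c.CDTDSpectrum(grid3, w / w.sum())
        bt = 3000.0 * np.eye(3) / 3
        vals = [
            c.signal_btensor_3d(spec, Rotation.random(random_state=s).as_matrix(), bt)
            for s in range(4)
        ]
        assert np.ptp(vals) < 1e-12

    def test_weightings_sum_to_trace(self, spec3):
        F = Rotation.random(random_state=5).as_matrix()
        bt = c.btensor_from_sde(4500.0, np.array([0.0, 0.6, 0.8]))
        w = np.einsum("ji,jk,ki->i", F, bt, F)
        assert w.sum() == pytest.approx(np.trace(bt), rel=1e-12)

    def test_non_orthonormal_frame_rejected(self, spec3):
        with pytest.raises(ValueError):
            c.signal_btensor_3d(spec3, np.ones((3, 3)), np.zeros((3, 3)))


class TestSde3D:
    def test_b0_is_unity_for_normalized(self, spec3):
        assert c.signal_sde_3d(spec3, np.eye(3), 0.0, np.array([1.0, 0, 0])) == (
            pytest.approx(1.0, rel=1e-12)
        )

    def test_delta_spectrum_is_dti_signal(self, grid3):
        spec = delta_spectrum(grid3, (5, 3, 1))
        lam = np.array([grid3.nodes[0][5], grid3.nodes[1][3], grid3.nodes[2][1]])
        F = Rotation.random(random_state=7).as_matrix()
        g = np.array([0.0, 0.0, 1.0])
        b = 2500.0
        gp = F.T @ g
        expect = np.exp(-b * B_LAMBDA_SCALE * float(gp**2 @ lam))
        assert c.signal_sde_3d(spec, F, b, g) == pytest.approx(expect, rel=1e-12)

    def test_matches_dense_quadrature_oracle(self, protocol112):
        # independent brute-force: direct summation of p * exp(-b g'^2 lam)
        # over all nodes of a fine 48^3 grid, fully vectorized
        fine = c.SpectralGrid.logspaced(3, 48)
        gt = c.mixture_3d_default(fine).normalized()
        F = np.eye(3)
        got = c.scheme_signals(gt, protocol112, frame=F)
        lam = fine.meshnodes()
        p = gt.flat()
        b = protocol112.bvals
        g = protocol112.bvecs
        expo = (b[:, None] * (g**2 @ lam.T)) * B_LAMBDA_SCALE
        oracle = np.exp(-expo) @ p
        assert np.allclose(got, oracle, rtol=1e-12, atol=1e-14)


class TestSde2D:
    def test_parallel_gradient_pure_radial(self, gt2d, radial_x):
        spec = gt2d.normalized()
        b = 3000.0
        got = c.signal_sde_2d(spec, radial_x, b, radial_x)
        lr = spec.grid.nodes[0]
        expect = float(spec.weights.sum(axis=1) @ np.exp(-b * lr * B_LAMBDA_SCALE))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_perpendicular_gradient_pure_tangential(self, gt2d, radial_x):
        spec = gt2d.normalized()
        b = 3000.0
        got = c.signal_sde_2d(spec, radial_x, b, np.array([0.0, 1.0, 0.0]))
        lt = spec.grid.nodes[1]
        expect = float(spec.weights.sum(axis=0) @ np.exp(-b * lt * B_LAMBDA_SCALE))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_axisymmetric_3d_consistency(self, small_scheme):
        # a 3D spectrum with lambda2 = lambda3 = lambda_t must reproduce the
        # 2D model exactly for any gradient
        g2 = c.SpectralGrid.logspaced(2, 6)
        rng = np.random.default_rng(3)
        w2 = rng.random(g2.shape)
        spec2 = c.CDTDSpectrum(g2, w2 / w2.sum())
        g3 = c.SpectralGrid(
            (g2.nodes[0], g2.nodes[1], g2.nodes[1]),
            ("lambda1", "lambda2", "lambda3"),
        )
        w3 = np.zeros(g3.shape)
        for i in range(g2.shape[0]):
            for j in range(g2.shape[1]):
                w3[i, j, j] = w2[i, j] / w2.sum()
        spec3 = c.CDTDSpectrum(g3, w3)
        rd = np.array([1.0, 0, 0])
        s2 = c.scheme_signals(spec2, small_scheme, radial_dir=rd)
        s3 = c.scheme_signals(spec3, small_scheme, frame=np.eye(3))
        assert np.allclose(s2, s3, rtol=1e-12)


class TestSignal1D:
    def test_delta_is_monoexponential(self):
        g1 = c.SpectralGrid.logspaced(1, 12)
        spec = delta_spectrum(g1, (4,))
        lam = float(g1.nodes[0][4])
        assert c.signal_1d(spec, 3000.0) == pytest.approx(
            np.exp(-3.0 * lam), rel=1e-12
        )

    def test_two_pool_mean(self):
        g1 = c.SpectralGrid.logspaced(1, 12)
        w = np.zeros(12)
        w[2] = w[9] = 0.5
        spec = c.CDTDSpectrum(g1, w)
        la, lb = g1.nodes[0][2], g1.nodes[0][9]
        expect = 0.5 * (np.exp(-2.0 * la) + np.exp(-2.0 * lb))
        assert c.signal_1d(spec, 2000.0) == pytest.approx(expect, rel=1e-12)

    def test_direction_independent(self, small_scheme):
        g1 = c.SpectralGrid.logspaced(1, 8)
        rng = np.random.default_rng(2)
        w = rng.random(8)
        spec = c.CDTDSpectrum(g1, w / w.sum())
        sig = c.scheme_signals(spec, small_scheme)
        by_b = {}
        for e, s in zip(small_scheme.encodings, sig):
            by_b.setdefault(e.b, set()).add(round(float(s), 15))
        assert all(len(v) == 1 for v in by_b.values())


class TestInvariances:
    def test_monotone_in_b(self, gt2d, radial_x):
        spec = gt2d.normalized()
        g = np.array([0.6, 0.8, 0.0])
        sig = [c.signal_sde_2d(spec, radial_x, b, g) for b in np.linspace(0, 10000, 25)]
        assert np.all(np.diff(sig) <= 1e-15)

    def test_diffusivity_bvalue_scale_invariance(self, gt2d, radial_x, protocol112):
        # scaling all diffusivities by 3 and all b-values by 1/3 leaves every
        # attenuation unchanged (bmax 10,000 -> 3,333 s/mm^2)
        spec = gt2d.normalized()
        s1 = c.scheme_signals(spec, protocol112, radial_dir=radial_x)
        scaled_grid = c.SpectralGrid(
            tuple(ax * 3.0 for ax in gt2d.grid.nodes), gt2d.grid.names
        )
        scaled_spec = c.CDTDSpectrum(scaled_grid, spec.weights)
        scaled_scheme = c.AcquisitionScheme.from_tables(
            protocol112.bvals / 3.0, protocol112.bvecs
        )
        s2 = c.scheme_signals(scaled_spec, scaled_scheme, radial_dir=radial_x)
        assert np.allclose(s1, s2, rtol=1e-12)
        assert scaled_scheme.bvals.max() == pytest.approx(10000 / 3.0)

    def test_joint_rotation_invariance(self, small_scheme):
        grid3 = c.SpectralGrid.logspaced(3, 6)
        rng = np.random.default_rng(8)
        w = rng.random(grid3.shape)
        spec = c.CDTDSpectrum(grid3, w / w.sum())
        F = Rotation.random(random_state=1).as_matrix()
        R = Rotation.random(random_state=9).as_matrix()
        s1 = c.scheme_signals(spec, small_scheme, frame=F)
        rot = c.AcquisitionScheme.from_tables(
            small_scheme.bvals, small_scheme.bvecs @ R.T
        )
        s2 = c.scheme_signals(spec, rot, frame=R @ F)
        assert np.allclose(s1, s2, atol=1e-10)
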