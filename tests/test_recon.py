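"""Spectral inversion: design matrix, regularized NNLS, volume pipeline."""

import numpy as np
import pytest

import cortecs as c
from cortecs.frames import weights_from_direction
from cortecs.recon import DEFAULT_ALPHA_LADDER


@pytest.fixture(scope="module")
def design2d(protocol112, grid2d_12, radial_x):
    w = weights_from_direction(radial_x, protocol112)
    return c.build_design_matrix(w, grid2d_12)


class TestDesignMatrix:
    def test_b0_row_all_ones(self, grid2d_12):
        scheme = c.AcquisitionScheme.from_tables(
            np.array([0.0, 1000.0]), np.array([[1.0, 0, 0], [0, 1.0, 0]])
        )
        A = c.build_design_matrix(
            weights_from_direction(np.array([1.0, 0, 0]), scheme), grid2d_12
        )
        assert np.allclose(A.entries[0], 1.0)
        assert np.all(A.entries > 0) and np.all(A.entries <= 1)

    def test_single_node_entry_by_construction(self):
        grid = c.SpectralGrid((np.array([0.5]), np.array([0.5])))
        scheme = c.AcquisitionScheme.from_tables(
            np.array([2000.0]), np.array([[1.0, 0, 0]])
        )
        A = c.build_design_matrix(
            weights_from_direction(np.array([1.0, 0, 0]), scheme), grid
        )
        # wr = b, wt = 0: entry = exp(-b * lambda_r * 1e-3)
        assert A.entries[0, 0] == pytest.approx(np.exp(-2000 * 0.5 * 1e-3), rel=1e-12)

    def test_adjoint_consistency_with_forward_model(
        self, design2d, protocol112, gt2d, radial_x
    ):
        # A @ p must equal the forward simulator exactly: shared discretization
        spec = gt2d.normalized()
        via_design = design2d.entries @ spec.flat()
        via_forward = c.scheme_signals(spec, protocol112, radial_dir=radial_x)
        assert np.allclose(via_design, via_forward, rtol=1e-12, atol=1e-14)

    def test_dimension_mismatch_rejected(self, protocol112, radial_x):
        w = weights_from_direction(radial_x, protocol112)
        with pytest.raises(ValueError):
            c.build_design_matrix(w, c.SpectralGrid.logspaced(3, 6))


class TestSolveRegularizedNnls:
    def test_monoexponential_on_node_exact(self, design2d, protocol112, grid2d_12,
                                           radial_x):
        truth = np.zeros(grid2d_12.shape)
        truth[6, 6] = 0.75  # s0 absorbed in total mass
        sig = design2d.entries @ truth.ravel()
        spec = c.solve_regularized_nnls(design2d, sig, alpha=0.0)
        assert spec.mass == pytest.approx(0.75, abs=1e-6)
        assert spec.weights[6, 6] == pytest.approx(0.75, abs=1e-6)

    def test_exact_recovery_three_node_support(self, design2d, grid2d_12):
        # any spectrum supported on <= 3 nodes is identifiable from the 112
        # noiseless encodings
        truth = np.zeros(grid2d_12.shape)
        truth[8, 4] = 0.5
        truth[4, 9] = 0.3
        truth[10, 10] = 0.2
        sig = design2d.entries @ truth.ravel()
        spec = c.solve_regularized_nnls(design2d, sig, alpha=0.0)
        assert np.abs(spec.weights - truth).max() <= 1e-3

    def test_two_node_mixture_mass_split(self, design2d, grid2d_12):
        truth = np.zeros(grid2d_12.shape)
        truth[9, 5] = 0.6
        truth[5, 8] = 0.4
        sig = design2d.entries @ truth.ravel()
        spec = c.solve_regularized_nnls(design2d, sig, alpha=0.0)
        assert spec.weights[9, 5] == pytest.approx(0.6, abs=1e-4)
        assert spec.weights[5, 8] == pytest.approx(0.4, abs=1e-4)

    def test_shrinkage_limit(self, design2d, protocol112, gt2d, radial_x):
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        spec = c.solve_regularized_nnls(design2d, sig, alpha=1e6)
        assert spec.mass < 1e-4

    def test_zero_signal_warns(self, design2d):
        with pytest.warns(UserWarning, match="all-zero"):
            spec = c.solve_regularized_nnls(design2d, np.zeros(112), alpha=0.1)
        assert spec.mass == 0.0

    def test_deterministic(self, design2d, protocol112, gt2d, radial_x):
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        a = c.solve_regularized_nnls(design2d, sig, alpha=0.01)
        b = c.solve_regularized_nnls(design2d, sig, alpha=0.01)
        assert np.array_equal(a.weights, b.weights)

    def test_non_negative_by_construction(self, design2d, protocol112, gt2d,
                                          radial_x):
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        noisy = c.add_rician_noise(sig, 50.0, seed=1)
        spec = c.solve_regularized_nnls(design2d, noisy, alpha=0.01)
        assert np.all(spec.weights >= 0)

    def test_dti_limit_mean_diffusivities(self, design2d, grid2d_12, protocol112,
                                          radial_x):
        # noiseless single-tensor (delta-spectrum) data: the mass-weighted
        # mean log-diffusivities must land within one grid spacing
        lr, lt = 0.9, 0.35
        b = protocol112.bvals
        cos2 = (protocol112.bvecs @ radial_x) ** 2
        sig = np.exp(-(b * cos2 * lr + b * (1 - cos2) * lt) * 1e-3)
        spec = c.solve_regularized_nnls(design2d, sig, alpha=0.0).normalized()
        lam = grid2d_12.meshnodes()
        p = spec.flat()
        mean_log = (p @ np.log(lam)) / p.sum()
        step = grid2d_12.log_spacing()
        assert abs(mean_log[0] - np.log(lr)) <= step
        assert abs(mean_log[1] - np.log(lt)) <= step


class TestSelectAlpha:
    def test_noiseless_representable_selects_small_alpha(self, design2d, grid2d_12):
        truth = np.zeros(grid2d_12.shape)
        truth[7, 7] = 1.0
        sig = design2d.entries @ truth.ravel()
        alpha = c.select_alpha(design2d, sig, DEFAULT_ALPHA_LADDER)
        spec = c.solve_regularized_nnls(design2d, sig, alpha)
        resid = np.linalg.norm(design2d.entries @ spec.flat() - sig)
        assert resid <= 1e-3

    def test_noisy_alpha_beats_unregularized_jsd(self, design2d, protocol112, gt2d,
                                                 radial_x):
        # over repeated noise draws at SNR 50, the L-curve choice must give a
        # mean spectrum at least as close (JSD) to truth as alpha = 0
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        rng = np.random.default_rng(6)
        alpha = None
        acc_reg = np.zeros(gt2d.grid.shape)
        acc_raw = np.zeros(gt2d.grid.shape)
        n = 20
        for _ in range(n):
            noisy = c.add_rician_noise(sig, 50.0, seed=rng)
            if alpha is None:
                alpha = c.select_alpha(design2d, noisy, DEFAULT_ALPHA_LADDER)
            acc_reg += c.solve_regularized_nnls(design2d, noisy, alpha).normalized().weights
            acc_raw += c.solve_regularized_nnls(design2d, noisy, 0.0).normalized().weights
        gt_norm = gt2d.normalized().weights
        assert c.spectrum_jsd(acc_reg / n, gt_norm) <= c.spectrum_jsd(acc_raw / n, gt_norm)

    def test_degenerate_three_candidates(self, design2d, protocol112, gt2d, radial_x):
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        cand = [1e-3, 1e-2, 1e-1]
        assert c.select_alpha(design2d, sig, cand) in cand

    def test_too_few_candidates_rejected(self, design2d):
        with pytest.raises(ValueError):
            c.select_alpha(design2d, np.ones(112), [0.1, 0.2])


class TestReconstructVolume:
    def test_single_voxel_phantom_three_local_maxima(self, protocol112, gt2d,
                                                     radial_x):
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        cfg = c.ReconConfig(grid=gt2d.grid, alpha=0.0, mode="2d")
        res = c.reconstruct_volume(
            sig.reshape(1, 1, 1, -1), protocol112, cfg,
            radial_dirs=radial_x.reshape(1, 1, 1, 3),
            frames=np.eye(3).reshape(1, 1, 1, 3, 3),
        )
        spec = c.CDTDSpectrum(gt2d.grid, res["spectra"][0, 0, 0].reshape(gt2d.grid.shape))
        assert len(c.find_peaks(spec, 0.05)) == 3

    def test_empty_mask_empty_output(self, protocol112, grid2d_12):
        cfg = c.ReconConfig(grid=grid2d_12, alpha=0.01, mode="2d",
                            mask=np.zeros((2, 2, 1), dtype=bool))
        res = c.reconstruct_volume(
            np.ones((2, 2, 1, 112)), protocol112, cfg,
            frames=np.broadcast_to(np.eye(3), (2, 2, 1, 3, 3)).copy(),
        )
        assert res["spectra"].sum() == 0.0
        assert res["n_skipped"] == 0

    def test_uniform_ground_truth_spatially_constant(self, protocol112, gt2d,
                                                     radial_x):
        sig = c.scheme_signals(gt2d.normalized(), protocol112, radial_dir=radial_x)
        dwis = np.broadcast_to(sig, (2, 2, 1, 112)).copy()
        cfg = c.ReconConfig(grid=gt2d.grid, alpha=0.01, mode="2d")
        res = c.reconstruct_volume(
            dwis, protocol112, cfg,
            radial_dirs=np.broadcast_to(radial_x, (2, 2, 1, 3)).copy(),
            frames=np.broadcast_to(np.eye(3), (2, 2, 1, 3, 3)).copy(),
        )
        flat = res["spectra"].reshape(4, -1)
        assert np.abs(flat - flat[0]).max() <= 1e-10
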