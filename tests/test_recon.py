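"""Radial Fourier operators, subspace encoding, ADMM/CG reconstructions, matching."""

import numpy as np
import pytest

from contrastnav.basis import SubspaceBasis, compute_svd_basis
from contrastnav.fingerprints import TissueParams, build_dictionary, default_schedules, default_tissue_grid
from contrastnav.motionsim import add_noise, make_coil_maps, make_phantom, simulate_kspace
from contrastnav.recon import (
    KSpaceData,
    SubspaceEncoder,
    final_recon,
    grid_positions,
    lowres_block_recon,
    match_parameters,
    nrmse,
    nufft_adjoint,
    nufft_forward,
)
from contrastnav.trajectory import build_plan, golden_angle_2d


@pytest.fixture(scope="module")
def small_plan():
    return golden_angle_2d(24, samples_per_spoke=16)


class TestFourierOperators:
    def test_delta_at_origin_gives_constant_magnitude(self, small_plan):
        img = np.zeros((16, 16), complex)
        img[8, 8] = 1.0  # grid center = Fourier origin
        y = nufft_forward(img, small_plan)
        assert np.allclose(np.abs(y), 1.0, atol=1e-12)

    def test_adjoint_dot_product_identity(self, small_plan, rng):
        x = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = rng.standard_normal((24, 16)) + 1j * rng.standard_normal((24, 16))
        lhs = np.vdot(y, nufft_forward(x, small_plan))
        rhs = np.vdot(nufft_adjoint(y, small_plan, (16, 16)), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_shift_theorem_on_delta(self, small_plan):
        """Moving a point source multiplies spokes by the exact linear phase."""
        img0 = np.zeros((16, 16), complex)
        img0[8, 8] = 1.0
        img1 = np.zeros((16, 16), complex)
        img1[10, 7] = 1.0  # shifted by (+2, -1)
        y0 = nufft_forward(img0, small_plan)
        y1 = nufft_forward(img1, small_plan)
        kc = small_plan.kcoords()
        phase = np.exp(-1j * (kc[..., 0] * 2 + kc[..., 1] * (-1)))
        assert np.abs(y1 - y0 * phase).max() < 1e-10

    def test_rotate_grid_consistency(self):
        """Sampling a rotated trajectory equals sampling the rotated image.

        The image is a sum of isotropic Gaussian blobs, whose rotation about
        the grid center is exact analytically (each blob's center moves), so
        no interpolation error enters the comparison.
        """
        n = 64
        c = n // 2
        centers = np.array([[10.0, 4.0], [-8.0, 7.0], [3.0, -12.0]])
        sigma = 3.0

        def blobs(ctrs):
            xx, yy = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
            img = np.zeros((n, n))
            for cx, cy in ctrs:
                img += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
            return img

        ang = np.deg2rad(17.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        plan = golden_angle_2d(80, samples_per_spoke=n)
        from dataclasses import replace

        plan_rot = replace(plan, spoke_dirs=plan.spoke_dirs @ R)
        y_rot_traj = nufft_forward(blobs(centers), plan_rot)
        y_rot_img = nufft_forward(blobs(centers @ R.T), plan)
        err = np.linalg.norm(y_rot_traj - y_rot_img) / np.linalg.norm(y_rot_traj)
        assert err < 1e-3


class TestSubspaceEncoder:
    def test_adjoint_consistency(self, rng):
        plan = build_plan(n_patterns=1, reps=3, spokes_per_block=10,
                          samples_per_spoke=12, pulses_per_block=20)
        U = np.linalg.qr(rng.standard_normal((20, 2)))[0]
        maps = make_coil_maps((12, 12), 2)
        enc = SubspaceEncoder(plan, U, (12, 12), coil_maps=maps)
        x = rng.standard_normal(enc.x_shape()) + 1j * rng.standard_normal(enc.x_shape())
        y = rng.standard_normal(enc.y_shape()) + 1j * rng.standard_normal(enc.y_shape())
        lhs = np.vdot(y, enc.forward(x))
        rhs = np.vdot(enc.adjoint(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_projection_energy_bounded(self, rng):
        """Coefficient representation never exceeds the full time-series energy."""
        U = np.linalg.qr(rng.standard_normal((50, 3)))[0]
        s = rng.standard_normal(50)
        assert np.linalg.norm(U.T @ s) <= np.linalg.norm(s) + 1e-12


class TestLowresBlockRecon:
    @pytest.fixture(scope="class")
    def problem(self):
        """Noiseless data generated exactly in the subspace model."""
        plan = build_plan(n_patterns=1, reps=4, spokes_per_block=48,
                          samples_per_spoke=16, pulses_per_block=48,
                          repeat_per_block=False)
        ph = make_phantom((16, 16), seed=5)
        sched = {1: default_schedules(1, 48)[0]}
        d = build_dictionary(default_tissue_grid(), sched[1])
        basis = compute_svd_basis(d, rank=2)
        gt = ph.coefficient_images(basis, sched[1])
        enc = SubspaceEncoder(plan, basis.U, (16, 16))
        x_blocks = np.broadcast_to(gt, (plan.n_blocks, *gt.shape))
        ks = KSpaceData(enc.forward(np.array(x_blocks)), plan)
        return ks, basis, gt

    def test_unregularized_recovery_is_exact(self):
        """lam=0 on a well-posed single-channel system recovers the truth exactly."""
        # kmax extended past pi*sqrt(2): the spokes then cover the grid's full
        # Cartesian spectrum (corners included) and the system is well-posed
        plan = build_plan(n_patterns=1, reps=3, spokes_per_block=64,
                          samples_per_spoke=32, pulses_per_block=64,
                          kmax=np.pi * 1.5)
        ph = make_phantom((16, 16), seed=5)
        sched = {1: default_schedules(1, 64)[0]}
        d = build_dictionary(default_tissue_grid(), sched[1])
        U1 = compute_svd_basis(d, rank=1).U
        gt = ph.coefficient_images(SubspaceBasis(U1), sched[1])
        enc = SubspaceEncoder(plan, U1, (16, 16))
        xb = np.array(np.broadcast_to(gt, (plan.n_blocks, *gt.shape)))
        ks = KSpaceData(enc.forward(xb), plan)
        series = lowres_block_recon(ks, SubspaceBasis(U1), lam_t=0.0, lowres_factor=1,
                                    max_iter=60, cg_iter=10, grid_shape=(16, 16))
        for b in range(series.n_blocks):
            assert nrmse(series.x[b], gt) < 1e-6

    def test_huge_tv_forces_temporal_constancy(self, problem):
        ks, basis, gt = problem
        series = lowres_block_recon(ks, basis, lam_t=1e6, rho=1e6, lowres_factor=1,
                                    max_iter=80, cg_iter=10, grid_shape=(16, 16))
        diffs = np.abs(np.diff(series.x, axis=0)).max()
        assert diffs < 1e-6 * np.abs(series.x).max()

    def test_admm_objective_monotone(self, problem):
        ks, basis, gt = problem
        noisy = add_noise(ks, snr=10, seed=2)
        series = lowres_block_recon(noisy, basis, lam_t=0.3, rho=1.0, lowres_factor=1,
                                    max_iter=25, cg_iter=8, grid_shape=(16, 16))
        obj = series.objective[1]
        # allow tiny numerical wiggle; the trend must be non-increasing
        assert np.all(np.diff(obj) <= 1e-6 * obj[0])

    def test_negative_lambda_rejected(self, problem):
        ks, basis, _ = problem
        with pytest.raises(ValueError):
            lowres_block_recon(ks, basis, lam_t=-1.0)


class TestFinalRecon:
    def test_zero_data_gives_zero_image(self, rng):
        plan = build_plan(n_patterns=1, reps=2, spokes_per_block=8,
                          samples_per_spoke=8, pulses_per_block=8)
        U = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        ks = KSpaceData(np.zeros((1, plan.n_spokes, 8), complex), plan)
        x = final_recon(ks, U, (8, 8))
        assert np.allclose(x, 0.0)

    def test_matches_lowres_pipeline_on_motion_free_phantom(self):
        """Static CG recon agrees with the per-block pipeline on motion-free data."""
        plan = build_plan(n_patterns=1, reps=3, spokes_per_block=64,
                          samples_per_spoke=32, pulses_per_block=64,
                          kmax=np.pi * 1.5)
        ph = make_phantom((16, 16), seed=6)
        sched = {1: default_schedules(1, 64)[0]}
        d = build_dictionary(default_tissue_grid(), sched[1])
        basis = compute_svd_basis(d, rank=2)
        ks = simulate_kspace(ph, plan, sched)
        x = final_recon(ks, basis.U, (16, 16), max_iter=60)
        series = lowres_block_recon(ks, basis, lam_t=0.0, lowres_factor=1,
                                    max_iter=30, cg_iter=10, grid_shape=(16, 16))
        assert nrmse(x, series.x.mean(axis=0)) < 0.05


class TestMatchParameters:
    @pytest.fixture(scope="class")
    def dict_and_basis(self):
        sched = default_schedules(1, 150)[0]
        d = build_dictionary(default_tissue_grid(), sched)
        return d, compute_svd_basis(d, rank=3)

    @pytest.fixture(scope="class")
    def separable_dict(self):
        """Coarse grid whose atoms stay distinguishable in rank-3 coordinates."""
        sched = default_schedules(1, 150)[0]
        grid = [
            TissueParams(0.3, 0.03),
            TissueParams(0.8, 0.08),
            TissueParams(2.0, 0.5),
            TissueParams(4.5, 2.0),
        ]
        d = build_dictionary(grid, sched)
        return d, compute_svd_basis(d, rank=3)

    def test_atom_self_match(self, dict_and_basis):
        d, basis = dict_and_basis
        k = 5
        c = (basis.U.conj().T @ d.signals[:, k]).reshape(3, 1, 1)
        maps = match_parameters(c, d, basis)
        assert maps["T1"][0, 0] == d.params[k].T1
        assert maps["T2"][0, 0] == d.params[k].T2
        assert np.isclose(maps["PD"][0, 0], d.params[k].PD)

    def test_scaled_atom_same_match_doubled_pd(self, dict_and_basis):
        d, basis = dict_and_basis
        k = 3
        c = 2.0 * (basis.U.conj().T @ d.signals[:, k]).reshape(3, 1, 1)
        maps = match_parameters(c, d, basis)
        assert maps["T1"][0, 0] == d.params[k].T1
        assert np.isclose(maps["PD"][0, 0], 2.0 * d.params[k].PD)

    def test_noisy_atoms_recover_grid_point(self, separable_dict, rng):
        """At SNR 20 the max-correlation match lands on the true atom nearly always."""
        d, basis = separable_dict
        n_trials = 1000
        hits = 0
        for _ in range(n_trials):
            k = rng.integers(d.n_atoms)
            c = basis.U.conj().T @ d.signals[:, k]
            # complex noise with total expected power (||c|| / 20)^2
            noise = rng.standard_normal(3) + 1j * rng.standard_normal(3)
            c_noisy = c + np.linalg.norm(c) / 20 * noise / np.sqrt(6)
            maps = match_parameters(c_noisy.reshape(3, 1, 1), d, basis)
            if maps["atom"][0, 0] == k:
                hits += 1
        assert hits / n_trials >= 0.95

    def test_empty_dictionary_rejected(self, dict_and_basis):
        d, basis = dict_and_basis
        with pytest.raises(ValueError):
            match_parameters(np.zeros((3, 1, 1)), d.subset("nope"), basis)
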