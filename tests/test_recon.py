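"""BSREM reconstruction: RDP correctness, MLEM equivalence, PRC effect, matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from garange.cohort import (CohortConfig, LesionPlanEntry, VoxelGrid,
                            build_patient, liver_noise_sphere)
from garange.projector import (SinogramGeometry, SystemModel,
                               build_system_operator, simulate_acquisition)
from garange.quant import cov
from garange.range_kernel import make_kernel
from garange.recon import ReconParams, match_beta, rdp, reconstruct


class TestRdp:
    def test_constant_image_zero_penalty_zero_gradient(self):
        pen, grad = rdp(np.full((5, 5, 3), 7.0))
        assert pen == 0.0
        assert np.all(grad == 0.0)

    def test_two_voxel_hand_example(self):
        """(x1, x2) = (2, 1), w = 1, gamma = 2: penalty = 1/(3+2) = 0.2."""
        img = np.array([[[2.0]], [[1.0]]])  # single neighbor pair along axis 0
        pen, _ = rdp(img, gamma=2.0, epsilon=0.0)
        assert pen == pytest.approx(0.2, abs=1e-12)

    def test_gradient_matches_central_difference(self, rng):
        img = rng.random((4, 4, 3)) + 0.5
        _, grad = rdp(img, gamma=2.0)
        h = 1e-6
        for idx in [(0, 0, 0), (2, 1, 1), (3, 3, 2)]:
            up, down = img.copy(), img.copy()
            up[idx] += h
            down[idx] -= h
            numeric = (rdp(up, 2.0)[0] - rdp(down, 2.0)[0]) / (2 * h)
            assert grad[idx] == pytest.approx(numeric, rel=1e-5, abs=1e-8)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_degree_one_homogeneity(self, c):
        """RDP is homogeneous of degree 1: R(c x) = c R(x) (for eps = 0)."""
        rng = np.random.default_rng(7)
        img = rng.random((4, 4, 2)) + 0.1
        pen1, _ = rdp(img, gamma=2.0, epsilon=0.0)
        pen_c, _ = rdp(c * img, gamma=2.0, epsilon=0.0)
        assert pen_c == pytest.approx(c * pen1, rel=1e-9)

    def test_penalty_nonnegative_and_zero_only_when_flat(self, rng):
        img = rng.random((4, 4, 2))
        pen, _ = rdp(img)
        assert pen > 0


@pytest.fixture(scope="module")
def tiny_setup():
    grid = VoxelGrid((24, 24, 1), spacing=(4.0, 4.0, 4.0))
    cfg = CohortConfig(grid=grid,
                       lesion_plan=(LesionPlanEntry("soft", volume=1.5, uptake=12.0),))
    patient = build_patient(cfg, seed=21)
    system = SystemModel(geometry=SinogramGeometry(12, 24, 4.0, 1),
                         psf_fwhm=4.0, count_scale=4e4)
    sino = simulate_acquisition(patient, system, None, seed=3)
    return patient, system, sino


def dense_operator(op, shape, sino_shape):
    """Probe the system operator into an explicit dense matrix."""
    nvox = int(np.prod(shape))
    cols = []
    for j in range(nvox):
        e = np.zeros(nvox)
        e[j] = 1.0
        cols.append(op.apply(e.reshape(shape)).ravel())
    return np.stack(cols, axis=1)


def mlem_oracle(A, y, r, n_iter, x0):
    """Textbook multiplicative MLEM on the explicit matrix."""
    s = A.T @ np.ones(A.shape[0])
    x = x0.copy()
    for _ in range(n_iter):
        ybar = A @ x + r
        ratio = y / np.maximum(ybar, 1e-30)
        upd = A.T @ ratio
        pos = s > 0
        x = np.where(pos, x / np.where(pos, s, 1.0) * upd, x)
    return x


class TestMlemEquivalence:
    def test_beta_zero_single_subset_equals_mlem(self, tiny_setup):
        """Unregularized single-subset BSREM is exactly classical MLEM."""
        patient, system, sino = tiny_setup
        op = build_system_operator(patient, system, None)
        op.slice_scale = sino.slice_scale
        A = dense_operator(op, patient.grid.shape, sino.values.shape)
        y = sino.values.ravel()
        r = sino.background_mean.ravel()

        params = ReconParams(beta=0.0, n_iterations=5, n_subsets=1, relaxation=0.0)
        res = reconstruct(sino, patient, system, params)

        # replicate the package's uniform start inside the field of view
        s = A.T @ np.ones(A.shape[0])
        fov = s > 0
        x0 = np.where(fov, y.sum() / s.sum(), 0.0)
        x_oracle = mlem_oracle(A, y, r, 5, x0)
        ours = res.image_activity.ravel()
        scale = np.abs(x_oracle).max()
        assert np.all(np.abs(ours - x_oracle) <= 1e-10 * scale)

    def test_loglikelihood_monotone(self, tiny_setup):
        """MLEM Poisson log-likelihood is non-decreasing at every iteration."""
        patient, system, _ = tiny_setup
        for seed in (1, 2, 3):
            sino = simulate_acquisition(patient, system, None, seed=seed)
            res = reconstruct(sino, patient, system,
                              ReconParams(beta=0.0, n_iterations=25, n_subsets=1,
                                          relaxation=0.0))
            diffs = np.diff(res.objective_trace)
            assert np.all(diffs >= -1e-7 * np.abs(res.objective_trace[:-1]))

    def test_count_conservation(self):
        """Without attenuation/background, MLEM forward totals converge to the
        data total."""
        grid = VoxelGrid((24, 24, 1), spacing=(4.0, 4.0, 4.0))
        cfg = CohortConfig(grid=grid, lesion_plan=())
        patient = build_patient(cfg, seed=2)
        system = SystemModel(geometry=SinogramGeometry(12, 24, 4.0, 1),
                             psf_fwhm=0.0, count_scale=4e4,
                             attenuation_enabled=False, background_fraction=0.0)
        sino = simulate_acquisition(patient, system, None, seed=5)
        res = reconstruct(sino, patient, system,
                          ReconParams(beta=0.0, n_iterations=50, n_subsets=1,
                                      relaxation=0.0))
        op = build_system_operator(patient, system, None)
        op.slice_scale = sino.slice_scale
        fwd_total = op.apply(res.image_activity).sum()
        assert fwd_total == pytest.approx(sino.values.sum(), rel=0.005)

    def test_nonnegativity_and_finite_objective(self, tiny_setup):
        patient, system, sino = tiny_setup
        res = reconstruct(sino, patient, system,
                          ReconParams(beta=0.05, n_iterations=10, n_subsets=4))
        assert np.all(res.image >= 0)
        assert np.all(np.isfinite(res.objective_trace))

    def test_noiseless_uniform_cylinder_recovers_uniform(self):
        """EM on noiseless data of a flat water cylinder recovers a flat,
        quantitatively correct interior (edge ringing excluded by erosion)."""
        grid = VoxelGrid((32, 32, 1), spacing=(4.0, 4.0, 4.0))
        cfg = CohortConfig(grid=grid, lesion_plan=(),
                           suv_levels={"air": 0.0, "soft": 2.0, "liver": 2.0,
                                       "lung": 2.0, "bone": 2.0})
        patient = build_patient(cfg, seed=1)
        patient.mu_map = 0.0096 * (patient.labels > 0)  # uniform water
        system = SystemModel(geometry=SinogramGeometry(48, 32, 4.0, 1),
                             psf_fwhm=4.0, count_scale=1e5,
                             background_fraction=0.0)
        sino = simulate_acquisition(patient, system, None, noiseless=True)
        res = reconstruct(sino, patient, system,
                          ReconParams(beta=0.0, n_iterations=100, n_subsets=1,
                                      relaxation=0.0))
        from scipy import ndimage
        interior = ndimage.binary_erosion(
            patient.labels > 0, structure=np.ones((3, 3, 1), bool), iterations=4)
        vals = res.image[interior]
        assert vals.std() / vals.mean() < 0.01  # RMS nonuniformity < 1%
        assert vals.mean() == pytest.approx(2.0, rel=0.005)


class TestPrcEffect:
    def test_prc_restores_point_source_peak(self):
        """Reconstructing range-blurred data with the kernel in the loop gives
        a strictly higher peak than reconstructing without it."""
        grid = VoxelGrid((32, 32, 6), spacing=(2.73, 2.73, 2.80))
        cfg = CohortConfig(grid=grid,
                           lesion_plan=(LesionPlanEntry("lung", volume=0.5,
                                                        uptake=30.0),))
        patient = build_patient(cfg, seed=6)
        system = SystemModel(geometry=SinogramGeometry(16, 32, 2.73, 6),
                             count_scale=2e5)
        kern = make_kernel("Ga-68", grid.spacing, n_samples=150_000, seed=0)
        sino = simulate_acquisition(patient, system, kern, seed=11)
        base = ReconParams(beta=0.0, n_iterations=15, n_subsets=4)
        res_prc = reconstruct(sino, patient, system,
                              ReconParams(beta=0.0, n_iterations=15, n_subsets=4,
                                          prc_kernel=kern))
        res_non = reconstruct(sino, patient, system, base)
        lesion = patient.labels >= 10
        assert res_prc.image[lesion].max() > res_non.image[lesion].max()


@pytest.fixture(scope="module")
def match_setup():
    grid = VoxelGrid((40, 40, 6), spacing=(4.0, 4.0, 4.0))
    cfg = CohortConfig(grid=grid, lesion_plan=())
    patient = build_patient(cfg, seed=13)
    system = SystemModel(geometry=SinogramGeometry(24, 40, 4.0, 6),
                         count_scale=1e5)
    kern = make_kernel("Ga-68", grid.spacing, n_samples=150_000, seed=0)
    sino = simulate_acquisition(patient, system, kern, seed=17)
    params = ReconParams(beta=0.05, n_iterations=10, n_subsets=4)
    return patient, system, kern, sino, params


class TestBetaMatching:
    def test_cov_monotone_in_beta(self, match_setup):
        patient, system, kern, sino, params = match_setup
        from dataclasses import replace
        liver = liver_noise_sphere(patient)
        covs = []
        for beta in (0.01, 0.05, 0.2):
            res = reconstruct(sino, patient, system, replace(params, beta=beta))
            covs.append(cov(res.image, liver))
        assert covs[0] >= covs[1] >= covs[2]

    def test_matched_cov_within_tolerance(self, match_setup):
        """The matched PRC reconstruction's liver COV sits within 5% relative
        of the non-PRC reference."""
        patient, system, kern, sino, params = match_setup
        liver = liver_noise_sphere(patient)
        ref = reconstruct(sino, patient, system, params)
        ref_cov = cov(ref.image, liver)
        beta, achieved = match_beta(ref_cov, sino, patient, system, kern, params,
                                    (0.002, 0.4), liver)
        assert abs(achieved - ref_cov) / ref_cov <= 0.05
        assert 0.002 <= beta <= 0.4

    def test_unbracketed_reference_raises(self, match_setup):
        patient, system, kern, sino, params = match_setup
        liver = liver_noise_sphere(patient)
        with pytest.raises(ValueError, match="not bracketed"):
            match_beta(1e-4, sino, patient, system, kern, params,
                       (0.01, 0.02), liver)

    def test_invalid_subset_count_rejected(self, tiny_setup):
        patient, system, sino = tiny_setup
        with pytest.raises(ValueError, match="divide"):
            reconstruct(sino, patient, system,
                        ReconParams(n_subsets=5, n_iterations=1))
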