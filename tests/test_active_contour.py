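import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vertaseg as vs
from vertaseg import active_contour as ac

import oracles


SHARP_EPS = 1e-3  # epsilon for sharp-limit region means on a converged field


def quick_cv(max_iters=400):
    return ac.CVParams(max_iters=max_iters)


class TestHeaviside:
    def test_center_value(self):
        assert ac.heaviside(0.0, 2.0) == pytest.approx(0.5)

    @given(st.floats(-50, 50), st.floats(0.01, 5))
    def test_complement_symmetry(self, x, eps):
        assert ac.heaviside(x, eps) + ac.heaviside(-x, eps) == pytest.approx(1.0)

    def test_sharp_limit_approaches_step(self):
        assert ac.heaviside(5.0, 0.001) > 0.999
        # pointwise convergence to the step at shrinking widths
        for x in (-3.0, -0.7, 0.4, 2.0):
            gaps = [abs(ac.heaviside(x, e) - (1.0 if x >= 0 else 0.0)) for e in (1, 0.1, 0.01)]
            assert gaps[0] > gaps[1] > gaps[2]

    def test_strictly_increasing(self):
        xs = np.linspace(-4, 4, 41)
        h = ac.heaviside(xs, 1.0)
        assert np.all(np.diff(h) > 0)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError, match="invalid regularization width"):
            ac.heaviside(1.0, 0.0)

    def test_dirac_is_derivative_scale(self):
        # numeric derivative of H matches delta
        x, eps, h = 0.7, 0.5, 1e-6
        num = (ac.heaviside(x + h, eps) - ac.heaviside(x - h, eps)) / (2 * h)
        assert num == pytest.approx(ac.dirac(x, eps), rel=1e-6)


class TestRegionMeans:
    def test_two_phase_recovery(self):
        img = np.full((20, 20), 50.0)
        img[5:15, 5:15] = 200.0
        phi = np.where(img > 100, 1.0, -1.0) * 10.0
        c1, c2 = ac.cv_region_means(img, phi, epsilon=0.01)
        assert c1 == pytest.approx(200.0, abs=0.5)
        assert c2 == pytest.approx(50.0, abs=0.5)

    def test_uniform_image(self):
        img = np.full((6, 6), 100.0)
        phi = vs.circle_level_set(img.shape)
        assert ac.cv_region_means(img, phi) == pytest.approx((100.0, 100.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(0, 255, (4, 4))
        phi = rng.normal(0, 3, (4, 4))
        c1, c2 = ac.cv_region_means(img, phi, epsilon=1.0)
        oc1, oc2 = oracles.region_means(img, phi, 1.0)
        assert c1 == pytest.approx(oc1, rel=1e-12)
        assert c2 == pytest.approx(oc2, rel=1e-12)

    def test_degenerate_region_falls_back_to_global_mean(self):
        img = np.arange(36, dtype=float).reshape(6, 6)
        phi = np.full((6, 6), 1e9)  # outside weight ~ 0
        c1, c2 = ac.cv_region_means(img, phi, epsilon=1e-6)
        assert c2 == pytest.approx(img.mean())

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            ac.cv_region_means(np.zeros((4, 4)), np.zeros((5, 5)))


class TestCVEnergy:
    def test_zero_residual_on_matching_partition(self):
        img = np.full((16, 16), 40.0)
        img[4:12, 4:12] = 220.0
        # the arctan H has 1/phi tails, so an exactly matching partition needs
        # a steep field for the residual to vanish
        phi = np.where(img > 100, 1e9, -1e9)
        p = ac.CVParams(mu=0.0, nu=0.0, epsilon=0.01)
        assert ac.cv_energy(img, phi, p) <= 1e-6 * img.size

    def test_length_term_matches_circle_perimeter(self):
        # pure length energy of a signed-distance disk ~ mu * 2 pi r
        phi = vs.circle_level_set((64, 64), radius=10.0)
        mu = 7.0
        p = ac.CVParams(mu=mu, nu=0.0, lambda1=1e-12, lambda2=1e-12, epsilon=1.0)
        img = np.zeros((64, 64))
        e = ac.cv_energy(img, phi, p)
        assert e == pytest.approx(mu * 2 * np.pi * 10.0, rel=0.05)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        img = rng.uniform(0, 255, (6, 6))
        phi = rng.normal(0, 2, (6, 6))
        p = ac.CVParams(mu=3.0, nu=-1.5, lambda1=0.8, lambda2=1.7, epsilon=0.9)
        expected = oracles.cv_energy(img, phi, p.mu, p.nu, p.lambda1, p.lambda2, p.epsilon)
        assert ac.cv_energy(img, phi, p) == pytest.approx(expected, rel=1e-10)


class TestCVEvolve:
    def test_disk_recovery(self, disk_phantom, circle_init):
        img, truth = disk_phantom
        field, _ = ac.cv_evolve(img, circle_init, quick_cv())
        assert vs.dice(ac.binarize(field), truth) >= 0.99

    def test_recovered_means_close_to_truth(self, disk_phantom, circle_init):
        img, truth = disk_phantom
        field, _ = ac.cv_evolve(img, circle_init, quick_cv())
        c1, c2 = ac.cv_region_means(img, field, epsilon=SHARP_EPS)
        assert c1 == pytest.approx(img[truth == 1].mean(), abs=1.0)
        assert c2 == pytest.approx(img[truth == 0].mean(), abs=1.0)

    def test_ring_recovery_with_checkerboard_init(self, clean_phantom, checker_init):
        # interior contour (the trabecular hole) requires an init whose zero
        # level crosses it; the checkerboard does, the far circle does not
        img, truth = clean_phantom
        field, _ = ac.cv_evolve(img, checker_init, quick_cv())
        assert vs.dice(ac.binarize(field), truth) >= 0.99

    def test_energy_descent_after_burn_in(self, clean_phantom, checker_init):
        img, _ = clean_phantom
        _, history = ac.cv_evolve(img, checker_init, quick_cv(max_iters=200))
        assert oracles.max_relative_ascent(history) <= 1e-3

    def test_intensity_shift_invariance(self, disk_phantom, circle_init):
        img, _ = disk_phantom
        shifted = np.clip(img, 0, 235) + 20.0  # keep headroom, then shift
        f1, _ = ac.cv_evolve(np.clip(img, 0, 235), circle_init, quick_cv(200))
        f2, _ = ac.cv_evolve(shifted, circle_init, quick_cv(200))
        assert np.array_equal(ac.binarize(f1), ac.binarize(f2))

    def test_deterministic(self, disk_phantom, circle_init):
        img, _ = disk_phantom
        f1, h1 = ac.cv_evolve(img, circle_init, quick_cv(60))
        f2, h2 = ac.cv_evolve(img, circle_init, quick_cv(60))
        assert np.array_equal(f1, f2) and h1 == h2

    def test_single_sign_init_rejected(self):
        with pytest.raises(ValueError, match="both signs"):
            ac.cv_evolve(np.zeros((8, 8)), np.ones((8, 8)))

    def test_divergence_reported(self, disk_phantom, circle_init):
        img, _ = disk_phantom
        with pytest.raises(FloatingPointError, match="reduce dt"):
            ac.cv_evolve(img, circle_init, ac.CVParams(dt=1e200, max_iters=30))


class TestLBFFitting:
    def test_uniform_image(self):
        img = np.full((12, 12), 77.0)
        phi = vs.circle_level_set(img.shape)
        fit = ac.lbf_fitting_functions(img, phi)
        assert np.allclose(fit.g1, 77.0)
        assert np.allclose(fit.g2, 77.0)

    def test_local_means_far_from_boundary(self):
        img = np.full((40, 40), 50.0)
        img[:, 20:] = 200.0
        phi = np.where(img > 100, 4.0, -4.0)
        p = ac.LBFParams(sigma=2.0, epsilon=0.01)
        fit = ac.lbf_fitting_functions(img, phi, p)
        # >= 3 sigma from the phase boundary the local mean is the phase value
        assert np.allclose(fit.g1[:, 27:], 200.0, atol=1.0)
        assert np.allclose(fit.g2[:, :13], 50.0, atol=1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        img = rng.uniform(0, 255, (5, 5))
        phi = rng.normal(0, 2, (5, 5))
        p = ac.LBFParams(sigma=1.2, epsilon=1.0)
        fit = ac.lbf_fitting_functions(img, phi, p)
        og1, og2 = oracles.lbf_fitting(img, phi, 1.2, 1.0)
        assert np.allclose(fit.g1, og1, atol=1e-8)
        assert np.allclose(fit.g2, og2, atol=1e-8)


class TestLBFEnergy:
    def test_near_zero_on_matching_partition(self):
        img = np.full((20, 20), 40.0)
        img[5:15, 5:15] = 220.0
        phi = np.where(img > 100, 1e7, -1e7)  # steep field: see C-V note above
        p = ac.LBFParams(sigma=1.0, mu_reg=0.0, nu_len=0.0, epsilon=0.01)
        assert ac.lbf_energy(img, phi, p) <= 1e-4 * img.size

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(41)
        img = rng.uniform(0, 255, (5, 5))
        phi = rng.normal(0, 2, (5, 5))
        p = ac.LBFParams(sigma=1.5, lambda1=0.7, lambda2=1.3, mu_reg=0.0, nu_len=0.0,
                         epsilon=0.8)
        expected = oracles.lbf_energy(img, phi, 1.5, 0.7, 1.3, 0.8)
        assert ac.lbf_energy(img, phi, p) == pytest.approx(expected, rel=1e-6)

    def test_bias_field_hurts_global_fit_not_local(self, clean_phantom, bias_phantom):
        # on the true partition, a smooth bias field inflates the C-V residual
        # but leaves the small-sigma local fit near its unbiased level
        img_clean, truth = clean_phantom
        img_bias, _ = bias_phantom
        phi = np.where(truth == 1, 1e6, -1e6)  # steep field: true partition
        pcv = ac.CVParams(mu=0.0, nu=0.0)
        cv_clean = ac.cv_energy(img_clean, phi, pcv)
        cv_bias = ac.cv_energy(img_bias, phi, pcv)
        assert cv_bias > 3.0 * cv_clean
        plbf = ac.LBFParams(sigma=3.0, mu_reg=0.0, nu_len=0.0)
        lbf_clean = ac.lbf_energy(img_clean, phi, plbf)
        lbf_bias = ac.lbf_energy(img_bias, phi, plbf)
        assert lbf_bias < 1.5 * lbf_clean


class TestLBFEvolve:
    def test_clean_phantom_recovery(self, clean_phantom, circle_init):
        img, truth = clean_phantom
        field, _ = ac.lbf_evolve(img, circle_init)
        assert vs.dice(ac.binarize(field), truth) >= 0.98

    def test_bias_phantom_beats_chan_vese(self, bias_phantom, circle_init):
        img, truth = bias_phantom
        lbf_field, _ = ac.lbf_evolve(img, circle_init)
        lbf_dice = vs.dice(ac.binarize(lbf_field), truth)
        cv_field, _ = ac.cv_evolve(img, circle_init, quick_cv())
        cv_dice = vs.dice(ac.binarize(cv_field), truth)
        assert lbf_dice >= 0.90
        assert cv_dice < lbf_dice

    def test_energy_descent_after_burn_in(self, clean_phantom, circle_init):
        img, _ = clean_phantom
        _, history = ac.lbf_evolve(img, circle_init, ac.LBFParams(max_iters=150))
        assert oracles.max_relative_ascent(history) <= 1e-3


class TestBinarize:
    def test_all_positive(self):
        assert np.all(ac.binarize(np.ones((4, 4))) == 1)

    def test_halfplane_boundary_column(self):
        cols = np.arange(10, dtype=float)
        phi = np.tile(cols - 4.3, (6, 1))  # phi = x - c, c = 4.3
        mask = ac.binarize(phi)
        assert np.all(mask[:, 5:] == 1)
        assert np.all(mask[:, :5] == 0)

    def test_negation_complements_except_zeros(self):
        rng = np.random.default_rng(9)
        phi = rng.normal(0, 1, (8, 8))
        phi[0, 0] = 0.0
        m, mn = ac.binarize(phi), ac.binarize(-phi)
        nonzero = phi != 0
        assert np.array_equal(m[nonzero], 1 - mn[nonzero])
        assert m[0, 0] == 1 and mn[0, 0] == 1  # ties belong inside
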