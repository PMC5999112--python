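"""Gaussian puff plume: release, growth, concentration, detection, fields."""

import math

import numpy as np
import pytest

from mothnav.plume import (
    PlumeModel,
    Puffs,
    advect_puffs,
    build_field,
    calibrate_threshold,
    concentration_at,
    detect,
    detectable_age_limit,
    detectable_radius,
    peak_concentration,
    puff_sigma,
    release_schedule,
)
from mothnav.wind import WindModel

# a free-growing puff model without the initial-size floor, convenient for
# closed-form checks
SHARP = dict(a_h=0.05, a_z=0.05, sigma_floor_m=1e-3, threshold=1e-6)


def single_puff(x=0.0, y=0.0):
    return Puffs(release_times=np.array([0.0]), centers=np.array([[x, y]]))


class TestReleaseSchedule:
    def test_examples(self):
        model = PlumeModel(pulse_interval_s=1.0)
        np.testing.assert_allclose(release_schedule(3.5, model), [0, 1, 2, 3])
        np.testing.assert_allclose(release_schedule(0.0, model), [0])

    def test_count_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            T = rng.uniform(0.2, 5.0)
            t_end = rng.uniform(0.0, 50.0)
            times = release_schedule(t_end, PlumeModel(pulse_interval_s=T))
            # brute-force enumeration
            expected, t = 0, 0.0
            while t <= t_end + 1e-12:
                expected += 1
                t += T
            assert len(times) == expected == math.floor(t_end / T) + 1
            assert np.all(times <= t_end + 1e-9)

    def test_invalid(self):
        with pytest.raises(ValueError):
            PlumeModel(pulse_interval_s=0.0)
        with pytest.raises(ValueError):
            release_schedule(-1.0, PlumeModel())


class TestPuffSigma:
    def test_linear_growth(self):
        model = PlumeModel(**SHARP)
        sh, sz = puff_sigma(10.0, model)
        assert sh == pytest.approx(0.5)
        assert sz == pytest.approx(0.5)

    def test_age_zero_hits_floor_not_zero(self):
        model = PlumeModel(a_h=0.05, a_z=0.05, sigma_floor_m=0.01)
        sh, sz = puff_sigma(0.0, model)
        assert sh == sz == 0.01

    def test_doubling_age_doubles_sigma_when_linear(self):
        model = PlumeModel(**SHARP)
        for a in (0.5, 2.0, 30.0):
            assert puff_sigma(2 * a, model)[0] == pytest.approx(2 * puff_sigma(a, model)[0])

    def test_negative_age_is_an_error(self):
        with pytest.raises(ValueError):
            puff_sigma(-0.1, PlumeModel())

    def test_strictly_increasing_in_age_past_floor(self):
        model = PlumeModel(a_h=0.02, a_z=0.02, sigma_floor_m=0.1)
        ages = np.linspace(6.0, 60.0, 50)  # floor region ends at age 5
        sh, _ = puff_sigma(ages, model)
        assert np.all(np.diff(sh) > 0)


class TestConcentration:
    def test_closed_form_at_center(self):
        # sigma_h = sigma_z = 0.5, m = 1: peak = ((2 pi)^{3/2} 0.25 * 0.5)^-1
        model = PlumeModel(**SHARP)
        c = concentration_at((0.0, 0.0), 10.0, single_puff(), model)
        assert c == pytest.approx(0.50790, rel=1e-4)
        assert peak_concentration(10.0, model) == pytest.approx(c)

    def test_gaussian_falloff_at_one_sigma(self):
        model = PlumeModel(**SHARP)
        c0 = concentration_at((0.0, 0.0), 10.0, single_puff(), model)
        c1 = concentration_at((0.5, 0.0), 10.0, single_puff(), model)
        assert c1 == pytest.approx(c0 * math.exp(-0.5), rel=1e-9)

    def test_superposition_of_colocated_puffs(self):
        model = PlumeModel(**SHARP)
        two = Puffs(release_times=np.array([0.0, 0.0]), centers=np.zeros((2, 2)))
        c1 = concentration_at((0.3, 0.1), 10.0, single_puff(), model)
        c2 = concentration_at((0.3, 0.1), 10.0, two, model)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_unreleased_puffs_do_not_exist(self):
        model = PlumeModel(**SHARP)
        future = Puffs(release_times=np.array([5.0]), centers=np.array([[0.0, 0.0]]))
        assert concentration_at((0, 0), 1.0, future, model) == 0.0

    def test_three_dimensional_integral_conserves_mass(self):
        """Quadrature of the trivariate Gaussian puff recovers m within 0.1%.

        Tensor Gauss-Legendre quadrature over an 8-sigma box, evaluating the
        field pointwise through the public interface.
        """
        model = PlumeModel(mass_per_pulse=2.0, **{**SHARP, "a_z": 0.08})
        age = 10.0
        sh, sz = puff_sigma(age, model)
        nodes, weights = np.polynomial.legendre.leggauss(40)
        xh, wh = nodes * 8 * sh, weights * 8 * sh
        xz, wz = nodes * 8 * sz, weights * 8 * sz
        puffs = single_puff()
        integral = 0.0
        for x, wx in zip(xh, wh):
            for y, wy in zip(xh, wh):
                plane = concentration_at((x, y), age, puffs, model)
                if plane < 1e-300:
                    continue
                col = sum(
                    wz_k * concentration_at((x, y), age, puffs, model, z=z_k)
                    for z_k, wz_k in zip(xz, wz)
                )
                integral += wx * wy * col
        assert integral == pytest.approx(2.0, rel=1e-3)


class TestDetection:
    def test_threshold_boundary_is_inclusive(self):
        model = PlumeModel(**SHARP)
        c = concentration_at((0.3, 0.0), 10.0, single_puff(), model)
        at = PlumeModel(**{**SHARP, "threshold": c})
        above = PlumeModel(**{**SHARP, "threshold": 2 * c})
        assert detect((0.3, 0.0), 10.0, single_puff(), at)
        assert not detect((0.3, 0.0), 10.0, single_puff(), above)

    def test_detectable_radius_closed_forms(self):
        model = PlumeModel(**SHARP)
        peak = peak_concentration(10.0, model)
        at_peak = PlumeModel(**{**SHARP, "threshold": peak})
        assert detectable_radius(10.0, at_peak) == pytest.approx(0.0, abs=1e-9)
        half_sig = PlumeModel(**{**SHARP, "threshold": peak * math.exp(-0.5)})
        assert detectable_radius(10.0, half_sig) == pytest.approx(0.5, rel=1e-9)

    def test_detect_agrees_with_detectable_radius(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.uniform(0.01, 0.2)
            age = rng.uniform(1.0, 30.0)
            model = PlumeModel(a_h=a, a_z=a, sigma_floor_m=1e-3, threshold=1.0)
            rho = detectable_radius(age, model)
            if np.isnan(rho):
                assert not detect((0.0, 0.0), age, single_puff(), model)
                continue
            eps = 1e-6 + 1e-6 * rho
            assert detect((rho - eps, 0.0), age, single_puff(), model)
            assert not detect((rho + eps, 0.0), age, single_puff(), model)

    def test_peak_decays_monotonically_and_stays_undetectable(self):
        model = PlumeModel(a_h=0.05, a_z=0.05, sigma_floor_m=0.05, threshold=1.0)
        ages = np.linspace(1.0, 100.0, 200)
        peaks = peak_concentration(ages, model)
        assert np.all(np.diff(peaks) <= 1e-12)
        a_limit = detectable_age_limit(model)
        assert np.all(peaks[ages > a_limit] < model.threshold)

    def test_higher_growth_rate_gives_larger_patch_at_fixed_threshold(self):
        # more turbulent flow (larger A) spreads puffs faster: larger
        # detectable area at a mid-range age, for one shared threshold
        lo = PlumeModel(a_h=0.0105, a_z=0.0105, sigma_floor_m=0.125, threshold=1.82)
        hi = PlumeModel(a_h=0.021, a_z=0.021, sigma_floor_m=0.125, threshold=1.82)
        assert detectable_radius(10.0, hi) > detectable_radius(10.0, lo)


def test_calibrate_threshold_reproduces_reference_radius():
    model = PlumeModel(a_h=0.0105, a_z=0.0105, sigma_floor_m=0.125, threshold=1.0)
    cstar = calibrate_threshold(model, u_mean=1.0, x_ref_m=10.0, rho_ref_m=0.3)
    calibrated = PlumeModel(
        a_h=0.0105, a_z=0.0105, sigma_floor_m=0.125, threshold=cstar
    )
    assert detectable_radius(10.0, calibrated) == pytest.approx(0.3, rel=1e-9)


class TestAdvection:
    def test_uniform_advection_is_exact(self, rng):
        wind = WindModel(u_mean=1.0, turbulence_intensity=0.0)
        puffs = single_puff()
        t, dt = 0.0, 0.1
        for _ in range(50):
            puffs = advect_puffs(puffs, wind, t, dt, rng)
            t += dt
        np.testing.assert_allclose(puffs.centers, [[5.0, 0.0]], atol=1e-12)

    def test_unreleased_puffs_stay_at_origin(self, rng):
        wind = WindModel(u_mean=1.0, turbulence_intensity=0.0)
        puffs = Puffs(release_times=np.array([0.0, 100.0]), centers=np.zeros((2, 2)))
        out = advect_puffs(puffs, wind, 1.0, 0.1, rng)
        assert out.centers[0, 0] > 0
        np.testing.assert_allclose(out.centers[1], [0.0, 0.0])

    def test_cross_stream_variance_grows_like_random_walk(self):
        """Ensemble variance of y-centers ~ n (TI U dt)^2 after n steps."""
        wind = WindModel(u_mean=1.0, turbulence_intensity=0.2)
        dt, n_puffs = 0.05, 400
        rng = np.random.default_rng(11)
        puffs = Puffs(
            release_times=np.zeros(n_puffs), centers=np.zeros((n_puffs, 2))
        )
        var_at = {}
        t = 0.0
        for step in range(1, 41):
            puffs = advect_puffs(puffs, wind, t, dt, rng)
            t += dt
            if step in (10, 40):
                var_at[step] = puffs.centers[:, 1].var()
        unit = (0.2 * 1.0 * dt) ** 2
        assert var_at[10] == pytest.approx(10 * unit, rel=0.5)
        assert var_at[40] == pytest.approx(40 * unit, rel=0.5)
        assert var_at[40] > var_at[10]


class TestPlumeField:
    def test_zero_turbulence_tracks_are_uniform_advection(self):
        wind = WindModel(u_mean=1.0, turbulence_intensity=0.0)
        plume = PlumeModel(a_h=0.02, a_z=0.02, threshold=3e-4, sigma_floor_m=0.125)
        field = build_field(wind, plume, 30.0, 0.05, 25.0, np.random.default_rng(0))
        for i in (0, 3, 10):
            n = field.lengths[i]
            ages = np.arange(n) * field.dt
            np.testing.assert_allclose(field.traj_x[i, :n], ages, atol=1e-9)
            np.testing.assert_allclose(field.traj_y[i, :n], 0.0, atol=1e-12)

    def test_field_detect_matches_module_level_detect(self):
        wind = WindModel(u_mean=1.0, turbulence_intensity=0.1)
        plume = PlumeModel(a_h=0.02, a_z=0.02, threshold=0.5, sigma_floor_m=0.125)
        field = build_field(wind, plume, 40.0, 0.05, 25.0, np.random.default_rng(5))
        t = 18.0
        puffs = field.live_puffs(t)
        for point in [(3.0, 0.0), (10.0, 0.1), (17.5, -0.4)]:
            assert field.detect(point, t) == detect(point, t, puffs, plume)
            assert field.concentration(point, t) == pytest.approx(
                concentration_at(point, t, puffs, plume)
            )

    def test_pulse_interval_must_align_with_dt(self):
        wind = WindModel()
        plume = PlumeModel(pulse_interval_s=1.0)
        with pytest.raises(ValueError):
            build_field(wind, plume, 10.0, 0.3, 25.0, np.random.default_rng(0))
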