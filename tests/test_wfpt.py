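import numpy as np
import pytest
from scipy.integrate import quad

from driftfit import (Boundary, DiffusionParams, absorption_probability,
                      fpt_cdf, fpt_density, predicted_signed_cdf,
                      sample_trials_euler)


class TestAbsorptionProbability:
    def test_zero_drift_limit_equals_relative_start_point(self):
        assert absorption_probability(
            DiffusionParams(v=0.0, a=0.2, zr=0.37)) == pytest.approx(0.37)
        assert absorption_probability(
            DiffusionParams(v=0.0, a=0.1, zr=0.5)) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # verified against the closed form and an Euler path simulation
        p = DiffusionParams(v=0.04, a=0.14, zr=0.66, s=0.1)
        assert absorption_probability(p) == pytest.approx(0.7756, abs=5e-4)

    def test_continuity_at_zero_drift(self):
        p_eps = DiffusionParams(v=1e-7, a=0.14, zr=0.3, s=0.1)
        assert absorption_probability(p_eps) == pytest.approx(0.3, abs=1e-4)

    def test_agrees_with_euler_simulation(self, rng):
        p = DiffusionParams(v=0.1, a=0.14, zr=0.5, s=0.1)
        n = 20_000
        upper, _ = sample_trials_euler(p, n, rng, dt=1e-4)
        p_up = absorption_probability(p)
        se = np.sqrt(p_up * (1 - p_up) / n)
        assert abs(upper.mean() - p_up) < 3.5 * se


class TestDensity:
    P = DiffusionParams(v=0.1, a=0.14, zr=0.5, s=0.1)

    def test_vanishes_at_short_times(self):
        assert fpt_density(1e-6, self.P, Boundary.UPPER) == pytest.approx(0.0)

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            fpt_density(0.0, self.P, Boundary.UPPER)
        with pytest.raises(ValueError):
            fpt_density(-1.0, self.P, Boundary.LOWER)

    def test_nonnegative_and_total_mass_one(self):
        t = np.linspace(1e-4, 10, 500)
        for b in Boundary:
            assert np.all(fpt_density(t, self.P, b) >= 0)
        total = sum(
            quad(lambda x: fpt_density(x, self.P, b), 1e-9, 30, limit=200)[0]
            for b in Boundary)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_per_boundary_mass_equals_absorption_probability(self):
        mass_up = quad(lambda x: fpt_density(x, self.P, Boundary.UPPER),
                       1e-9, 30, limit=200)[0]
        assert mass_up == pytest.approx(absorption_probability(self.P),
                                        abs=1e-6)

    def test_matches_euler_simulation(self, rng):
        # ECDF of Euler-simulated signed RTs vs the series-based CDF
        n = 20_000
        upper, rt = sample_trials_euler(self.P, n, rng, dt=1e-4)
        signed = np.sort(np.where(upper, rt, -rt))
        F = predicted_signed_cdf(signed, self.P)
        i = np.arange(1, n + 1)
        dist = np.max(np.maximum(i / n - F, F - (i - 1) / n))
        assert dist < 0.02  # MC noise ~0.01 at this n plus Euler step bias


class TestCdf:
    P = DiffusionParams(v=0.08, a=0.12, zr=0.4, s=0.1)

    def test_zero_at_origin(self):
        assert fpt_cdf(0.0, self.P, Boundary.UPPER) == 0.0

    def test_symmetric_split_without_drift(self):
        p = DiffusionParams(v=0.0, a=0.14, zr=0.5, s=0.1)
        for b in Boundary:
            assert fpt_cdf(50.0, p, b) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("t", [0.003, 0.02, 0.15, 0.6, 2.5])
    def test_matches_quadrature_of_density(self, t):
        for b in Boundary:
            num = quad(lambda x: fpt_density(x, self.P, b), 1e-12, t,
                       limit=200)[0]
            assert fpt_cdf(t, self.P, b) == pytest.approx(num, abs=1e-6)

    def test_nondecreasing(self):
        t = np.linspace(0, 8, 600)
        for b in Boundary:
            assert np.all(np.diff(fpt_cdf(t, self.P, b)) >= -1e-12)


class TestSignedCdf:
    def test_degenerate_mixture_reduces_to_fpt_cdf(self):
        p = DiffusionParams(v=0.06, a=0.14, zr=0.55, t0=0.35, s=0.1)
        p_lower = 1 - absorption_probability(p)
        for t in (0.5, 0.9, 2.0):
            up = predicted_signed_cdf(t, p)
            assert up == pytest.approx(
                p_lower + fpt_cdf(t - p.t0, p, Boundary.UPPER), abs=1e-9)
            lo = predicted_signed_cdf(-t, p)
            assert lo == pytest.approx(
                p_lower - fpt_cdf(t - p.t0, p, Boundary.LOWER), abs=1e-9)

    def test_limits(self):
        p = DiffusionParams(v=0.06, a=0.14, zr=0.55, t0=0.35, s=0.1)
        assert predicted_signed_cdf(1e6, p) == pytest.approx(1.0, abs=1e-8)
        assert predicted_signed_cdf(-1e6, p) == pytest.approx(0.0, abs=1e-8)

    def test_monotone_on_dense_grid_with_variability(self):
        p = DiffusionParams(v=0.05, a=0.12, zr=0.45, t0=0.4, sv=0.05,
                            sz=0.02, st=0.1, s=0.1)
        t = np.linspace(-6, 6, 1000)
        F = predicted_signed_cdf(t, p)
        assert np.all(np.diff(F) >= -1e-12)
        assert F[0] >= 0 and F[-1] <= 1

    def test_variability_mixture_matches_euler_simulation(self, rng):
        p = DiffusionParams(v=0.06, a=0.12, zr=0.5, t0=0.4, sv=0.05, s=0.1)
        n = 15_000
        upper, rt = sample_trials_euler(p, n, rng, dt=1e-4)
        signed = np.sort(np.where(upper, rt, -rt))
        F = predicted_signed_cdf(signed, p)
        i = np.arange(1, n + 1)
        dist = np.max(np.maximum(i / n - F, F - (i - 1) / n))
        assert dist < 0.025

    def test_invariant_under_rescaling(self, rng):
        t = np.linspace(-5, 5, 101)
        for _ in range(20):
            v = rng.uniform(-0.2, 0.2)
            a = rng.uniform(0.06, 0.25)
            zr = rng.uniform(0.2, 0.8)
            t0 = rng.uniform(0.1, 0.7)
            p = DiffusionParams(v=v, a=a, zr=zr, t0=t0, s=0.1)
            q = p.rescaled(rng.uniform(0.05, 2.0))
            np.testing.assert_allclose(predicted_signed_cdf(t, q),
                                       predicted_signed_cdf(t, p), atol=1e-8)
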