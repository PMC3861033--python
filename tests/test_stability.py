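"""Dispersion relation and polarization-capability predicates."""

import numpy as np
import pytest

from gdipol import (dispersion_growth_rate, diffusion_rescue, growth_spectrum,
                    homogeneous_steady_state, is_polarizable)
from gdipol.stability import radial_log_derivative, _bessel_i_ratio

TINY = 1e-300


@pytest.fixture(scope="module")
def reaction_free(p_control):
    q = p_control.replace(alpha1=TINY, alpha2=TINY, alpha3=TINY,
                          beta1=TINY, beta2=TINY, beta3=TINY,
                          gamma1=TINY, gamma2=TINY, delta1=TINY, delta2=TINY)
    return q, homogeneous_steady_state(q)


class TestRadialProfile:
    def test_zero_rate_limit_is_power_law(self, p_control):
        # phi ~ r^l at sigma = 0, so phi'/phi|_R = l/R
        for l in (0, 1, 4):
            assert radial_log_derivative(l, 0.0, 11.0, 3.95) == pytest.approx(l / 3.95)

    def test_continued_fraction_matches_scipy_on_real_axis(self):
        from scipy.special import spherical_in
        for l in (0, 1, 5, 12):
            for sigma in (1e-4, 0.01, 1.0):
                z = np.sqrt(sigma / 11.0) * 3.95
                cf = _bessel_i_ratio(l, complex(z))
                ref = spherical_in(l + 1, z) / spherical_in(l, z)
                assert cf == pytest.approx(ref, rel=1e-10)

    def test_analytic_continuation_is_continuous_through_zero(self):
        left = radial_log_derivative(2, -1e-8, 11.0, 3.95)
        right = radial_log_derivative(2, 1e-8, 11.0, 3.95)
        assert np.real(left) == pytest.approx(np.real(right), abs=1e-6)


class TestDispersion:
    def test_reaction_free_decay_is_pure_lateral_diffusion(self, p_control, reaction_free):
        q, base = reaction_free
        for l in (1, 2, 5, 10):
            s = dispersion_growth_rate(q, base, l)
            assert s.real == pytest.approx(-q.D2 * l * (l + 1) / q.R**2, rel=1e-6)

    def test_reaction_free_spectrum_decreases_with_degree(self, reaction_free):
        q, base = reaction_free
        spec = growth_spectrum(q, l_max=6, base=base, auto_extend=False)
        assert np.all(np.diff(spec.re) < 0)

    def test_control_cell_single_cluster_mode(self, p_control, base_control):
        spec = growth_spectrum(p_control, l_max=10, base=base_control)
        assert spec.dominant_l == 1
        assert spec.re[1] > 0
        assert np.all(spec.re[2:11] < 0)

    def test_mass_mode_is_neutral_at_l0(self, p_control, base_control):
        s0 = dispersion_growth_rate(p_control, base_control, 0)
        assert abs(s0.real) < 1e-8

    def test_reservoir_closure_exceeds_full_closure(self, p_control, base_control):
        """Neglecting cytosolic depletion under the growing cap removes a
        negative feedback, so the reservoir rate is the larger one."""
        full = dispersion_growth_rate(p_control, base_control, 1).real
        res = dispersion_growth_rate(p_control, base_control, 1,
                                     cytosol="reservoir").real
        assert res > full > 0

    def test_rate_continuous_under_small_parameter_changes(self, p_control, base_control):
        s0 = dispersion_growth_rate(p_control, base_control, 1).real
        for name in ("alpha3", "beta3", "gamma2"):
            q = p_control.scaled(name, 1.01)
            s = dispersion_growth_rate(q, homogeneous_steady_state(q), 1).real
            assert abs(s - s0) < 0.2 * abs(s0)

    @pytest.mark.parametrize("name,factor", [
        ("alpha3", 1 / 3), ("beta3", 1 / 3), ("N24", 3.0),
        ("NB", 3.0), ("gamma1", 3.0), ("D2", 1 / 3),
    ])
    def test_growing_structure_stays_single_cluster(self, p_control, name, factor):
        """Across wide single-parameter changes, whenever any mode grows
        the dominant one remains the single-cap degree l = 1."""
        q = p_control.scaled(name, factor)
        spec = growth_spectrum(q, l_max=10)
        if np.any(spec.re[1:] > 0):
            assert spec.dominant_l == 1


class TestCapability:
    def test_control_cell_is_polarizable(self, p_control, base_control):
        assert is_polarizable(p_control, base=base_control)

    def test_no_membrane_supply_cannot_pattern(self, p_control):
        q = p_control.replace(beta2=TINY, beta1=TINY, gamma1=TINY, delta1=TINY)
        assert not is_polarizable(q)

    def test_capability_lost_below_gef_threshold(self, p_control):
        """Bisection along N24 at control alpha3 finds a finite threshold
        below which polarization is impossible."""
        lo, hi = 0.3, 1.0
        assert is_polarizable(p_control.scaled("N24", hi))
        assert not is_polarizable(p_control.scaled("N24", lo))
        for _ in range(6):
            mid = 0.5 * (lo + hi)
            if is_polarizable(p_control.scaled("N24", mid)):
                hi = mid
            else:
                lo = mid
        assert 0.4 < 0.5 * (lo + hi) < 1.0

    def test_rescue_trivially_true_when_already_polarizable(self, p_control):
        assert diffusion_rescue(p_control)

    def test_feedback_failure_cannot_be_rescued_by_diffusion(self, p_control):
        """Deep in the failed-feedback regime (fast hydrolysis, little
        GEF) no diffusion constants restore patterning, and membrane
        Cdc42-GTP is essentially gone."""
        q = p_control.scaled("alpha3", 20.0).scaled("N24", 0.05)
        base = homogeneous_steady_state(q)
        assert not diffusion_rescue(q)
        assert base.cdc42gtp_fraction(q) < 1e-3
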