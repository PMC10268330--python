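import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protoendo.transport import (
    CompartmentSystem,
    ReleaseKineticsModel,
    SoluteSpec,
    VesicleGeometry,
    crossing_rate,
    crossing_time,
    fit_release_rate,
    molecular_flux,
    release_timecourse,
    sink_release_time,
    time_to_fraction,
)

TRINUCLEOTIDE = SoluteSpec("trinucleotide", 0.21e-12)
GUV_4UM = VesicleGeometry(4.0)


class TestFluxAndCrossing:
    def test_zero_gradient_zero_flux(self):
        assert molecular_flux(TRINUCLEOTIDE, 0.0) == 0.0

    def test_flux_value_at_1_mM(self):
        assert molecular_flux(TRINUCLEOTIDE, 1.0) == pytest.approx(
            2.1e-19, rel=1e-12)

    def test_flux_antisymmetric(self):
        assert molecular_flux(TRINUCLEOTIDE, -3.0) == -molecular_flux(
            TRINUCLEOTIDE, 3.0)

    def test_trinucleotide_crossing_rate_rounds_to_printed_value(self):
        rate = crossing_rate(TRINUCLEOTIDE, 1.0, GUV_4UM)
        assert float(f"{rate:.1g}") == 0.06

    def test_trinucleotide_crossing_time_rounds_to_16_s(self):
        assert round(crossing_time(TRINUCLEOTIDE, 1.0, GUV_4UM)) == 16

    @pytest.mark.parametrize("ps,expected,sig", [
        (1e-10, 0.03, 1), (1e-13, 33.0, 2)])
    def test_permeability_range_crossing_times(self, ps, expected, sig):
        t = crossing_time(SoluteSpec("nutrient", ps), 1.0, GUV_4UM)
        assert float(f"{t:.{sig}g}") == expected

    def test_zero_rate_gives_infinite_time(self):
        assert crossing_time(SoluteSpec("inert", 0.0), 1.0, GUV_4UM) == \
            float("inf")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(ps=st.floats(1e-14, 1e-9), dc=st.floats(0.01, 100.0),
           d=st.floats(0.5, 20.0))
    def test_rate_linear_in_ps_dc_and_area(self, ps, dc, d):
        s = SoluteSpec("s", ps)
        g = VesicleGeometry(d)
        base = crossing_rate(s, dc, g)
        assert crossing_rate(SoluteSpec("s", 10 * ps), dc, g) == \
            pytest.approx(10 * base, rel=1e-12)
        assert crossing_rate(s, 2 * dc, g) == pytest.approx(2 * base,
                                                            rel=1e-12)
        assert crossing_rate(s, dc, VesicleGeometry(2 * d)) == \
            pytest.approx(4 * base, rel=1e-12)

    def test_crossing_time_scales_inverse_squared_with_diameter(self):
        t1 = crossing_time(TRINUCLEOTIDE, 1.0, VesicleGeometry(4.0))
        t2 = crossing_time(TRINUCLEOTIDE, 1.0, VesicleGeometry(8.0))
        assert t2 == pytest.approx(t1 / 4, rel=1e-12)


def brute_force_release(system, t_end, n_steps=20_000):
    """Brute-force fine-step (classical RK4) integration of the
    two-membrane exchange ODEs; independent of the closed form."""
    k1, k2, k3 = system.rates
    cb = system.bath_concentration

    def rhs(c):
        return np.array([-k1 * (c[0] - c[1]),
                         k2 * (c[0] - c[1]) - k3 * (c[1] - cb)])

    c = np.array([system.compartment_concentration,
                  system.lumen_concentration])
    dt = t_end / n_steps
    for _ in range(n_steps):
        a = rhs(c)
        b = rhs(c + 0.5 * dt * a)
        d = rhs(c + 0.5 * dt * b)
        e = rhs(c + dt * d)
        c = c + dt / 6.0 * (a + 2 * b + 2 * d + e)
    return c


class TestReleaseTimecourse:
    def test_initial_concentrations_returned_exactly(self):
        sys_ = CompartmentSystem(0.5, 2.0, TRINUCLEOTIDE, 10.0, 1.0, 0.5)
        df = release_timecourse(sys_, [0.0])
        assert df.C_compartment_mM.iloc[0] == pytest.approx(10.0)
        assert df.C_lumen_mM.iloc[0] == pytest.approx(1.0)

    def test_long_time_limit_is_bath_concentration(self):
        sys_ = CompartmentSystem(0.5, 2.0, SoluteSpec("s", 1e-7), 10.0,
                                 0.0, 0.25)
        df = release_timecourse(sys_, [1e9])
        assert df.C_compartment_mM.iloc[0] == pytest.approx(0.25, rel=1e-6)
        assert df.C_lumen_mM.iloc[0] == pytest.approx(0.25, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_matches_fine_step_integrator(self, seed):
        rng = np.random.default_rng(seed)
        r_c = rng.uniform(0.2, 1.0)
        sys_ = CompartmentSystem(
            r_c, r_c + rng.uniform(0.5, 3.0),
            SoluteSpec("s", 10 ** rng.uniform(-10, -8)),
            rng.uniform(1, 20), rng.uniform(0, 5), rng.uniform(0, 2))
        k1, _, _ = sys_.rates
        t_end = 2.0 / k1
        ref = brute_force_release(sys_, t_end)
        df = release_timecourse(sys_, [t_end])
        got = np.array([df.C_compartment_mM.iloc[0], df.C_lumen_mM.iloc[0]])
        assert np.all(np.abs(got - ref) / np.abs(ref).max() < 1e-6)

    def test_closed_system_conserves_mass(self):
        sys_ = CompartmentSystem(0.5, 2.0, SoluteSpec("s", 1e-8), 10.0,
                                 0.5, 0.0, bath_exchange=False)
        r_c, r_l = 0.5e-4, 2.0e-4
        v_c = 4 / 3 * np.pi * r_c ** 3
        v_l = 4 / 3 * np.pi * r_l ** 3 - v_c
        df = release_timecourse(sys_, np.linspace(0, 1e7, 20))
        total = df.C_compartment_mM * v_c + df.C_lumen_mM * v_l
        assert np.all(np.abs(total / total.iloc[0] - 1) < 1e-9)

    def test_monotone_release_down_the_gradient(self):
        sys_ = CompartmentSystem(0.5, 2.0, SoluteSpec("s", 1e-8), 10.0,
                                 1.0, 0.0)
        df = release_timecourse(sys_, np.linspace(0, 1e7, 50))
        assert np.all(np.diff(df.C_compartment_mM) <= 1e-12)


class TestTimeToFraction:
    def test_zero_fraction_is_time_zero(self):
        sys_ = CompartmentSystem(0.5, 2.0, TRINUCLEOTIDE, 10.0)
        assert time_to_fraction(sys_, 0.0) == 0.0

    def test_fraction_one_rejected(self):
        sys_ = CompartmentSystem(0.5, 2.0, TRINUCLEOTIDE, 10.0)
        with pytest.raises(ValueError):
            time_to_fraction(sys_, 1.0)

    def test_sink_limit_time_constant(self):
        """Lumen as infinite sink: k = 3 P_s / r, so the 1 - 1/e point
        sits at t = r/(3 P_s)."""
        solute = SoluteSpec("s", 1e-9)
        sys_ = CompartmentSystem(0.5, 5000.0, solute, 10.0, 0.0, 0.0,
                                 bath_exchange=False)
        f = 1 - 1 / np.e
        expected = 0.5e-4 / (3 * 1e-9)
        assert time_to_fraction(sys_, f) == pytest.approx(expected, rel=1e-3)
        assert sink_release_time(0.5, solute, f) == pytest.approx(
            expected, rel=1e-12)

    def test_sink_limit_90_percent_at_reported_permeability(self):
        """General machinery check: at the trinucleotide permeability a
        0.5-um compartment releases 90% into a sink after
        ln(10)*r/(3*P_s) ~ 1.8e8 s."""
        t90 = sink_release_time(0.5, TRINUCLEOTIDE, 0.9)
        assert t90 == pytest.approx(np.log(10) * 0.5e-4 / (3 * 0.21e-12),
                                    rel=1e-12)
        assert t90 == pytest.approx(1.83e8, rel=0.005)


class TestFitReleaseRate:
    def test_exact_exponential_recovered_by_both_modes(self):
        t = np.linspace(0, 48, 9)
        r = 5.0 * np.exp(-0.04 * t)
        assert fit_release_rate(t, r, "two_point") == pytest.approx(
            0.04, abs=1e-10)
        assert fit_release_rate(t, r, "least_squares") == pytest.approx(
            0.04, abs=1e-10)

    @pytest.mark.parametrize("r0,rt,expected", [
        (36.3, 14.3, 0.0388),   # compartment vs lumen over 24 h
        (6.2, 3.9, 0.0193),     # compartment vs external medium
    ])
    def test_intensity_ratio_pairs(self, r0, rt, expected):
        k = fit_release_rate([0.0, 24.0], [r0, rt], "two_point")
        assert k == pytest.approx(np.log(r0 / rt) / 24, rel=1e-12)
        assert k == pytest.approx(expected, abs=5e-4)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            fit_release_rate([0, 1], [1.0, 0.0])

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            fit_release_rate([2.0, 2.0], [3.0, 1.0], "two_point")


class TestReleaseKineticsModel:
    def test_fit_recovers_noise_free_rate(self):
        t = np.linspace(0, 24, 9)
        res = ReleaseKineticsModel(t, 36.3 * np.exp(-0.0388 * t)).fit()
        assert res.rate_per_h == pytest.approx(0.0388, abs=1e-8)
        assert res.initial_ratio == pytest.approx(36.3, rel=1e-8)
        assert "rate k (1/h)" in res.summary()

    def test_predict_round_trip(self):
        t = np.linspace(0, 24, 9)
        res = ReleaseKineticsModel(t, 10 * np.exp(-0.1 * t)).fit()
        assert np.allclose(res.predict(t), 10 * np.exp(-0.1 * t))
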