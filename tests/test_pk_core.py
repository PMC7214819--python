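import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from teicopk.pk_core import (
    DoseEvent,
    IndividualParams,
    conc_profiles,
    conc_single_infusion,
    micro_constants,
    secondary_params,
    simulate_profile,
)


def ode_profile(p: IndividualParams, doses, times):
    """Independent oracle: stiff ODE integration of the two-compartment
    infusion system (amounts A1, A2)."""
    mc = micro_constants(p)

    def rate_in(t):
        return sum(d.rate for d in doses if d.start_time <= t < d.end_time)

    def rhs(t, a):
        a1, a2 = a
        return [
            rate_in(t) - (mc.k10 + mc.k12) * a1 + mc.k21 * a2,
            mc.k12 * a1 - mc.k21 * a2,
        ]

    # integrate piecewise between infusion switch points for accuracy
    switches = sorted({0.0, *[d.start_time for d in doses], *[d.end_time for d in doses], *times})
    out = {}
    a = [0.0, 0.0]
    for lo, hi in zip(switches[:-1], switches[1:]):
        if hi <= lo:
            continue
        eval_ts = [t for t in times if lo < t <= hi]
        sol = solve_ivp(
            rhs, (lo, hi), a, method="Radau", rtol=1e-10, atol=1e-12,
            t_eval=eval_ts or None, dense_output=False,
        )
        for t, col in zip(sol.t, sol.y.T):
            out[t] = col[0] / p.V1
        sol_end = solve_ivp(rhs, (lo, hi), a, method="Radau", rtol=1e-10, atol=1e-12)
        a = sol_end.y[:, -1]
    return np.array([out.get(t, 0.0) for t in times])


class TestMicroConstants:
    def test_typical_values(self, typical_params):
        mc = micro_constants(typical_params)
        assert mc.k10 == pytest.approx(0.05628, abs=5e-6)
        assert mc.k12 == pytest.approx(0.09957, abs=5e-6)
        assert mc.k21 == pytest.approx(0.01421, abs=5e-6)

    def test_unit_params(self):
        mc = micro_constants(IndividualParams(V1=1, V2=1, Q=1, CL=1))
        assert (mc.k10, mc.k12, mc.k21) == (1.0, 1.0, 1.0)

    def test_zero_cl_rejected(self):
        with pytest.raises(ValueError):
            IndividualParams(V1=2, V2=4, Q=1, CL=0)


class TestSecondaryParams:
    def test_terminal_half_life(self, typical_params):
        sp = secondary_params(typical_params)
        assert sp.t_half_beta == pytest.approx(143.2, abs=0.5)
        assert 30.0 <= sp.t_half_beta <= 180.0  # literature elimination range

    def test_vss(self, typical_params):
        assert secondary_params(typical_params).Vss == pytest.approx(18.50)

    def test_root_identities(self, typical_params):
        sp = secondary_params(typical_params)
        mc = micro_constants(typical_params)
        assert sp.alpha > sp.beta > 0
        assert sp.alpha + sp.beta == pytest.approx(mc.k10 + mc.k12 + mc.k21)
        assert sp.alpha * sp.beta == pytest.approx(mc.k10 * mc.k21)

    def test_one_compartment_limit(self):
        p = IndividualParams(V1=2.31, V2=1e-8, Q=1e-10, CL=0.13)
        sp = secondary_params(p)
        assert sp.t_half_alpha == pytest.approx(np.log(2) * 2.31 / 0.13, rel=1e-4)


class TestSingleInfusion:
    def test_zero_before_and_at_start(self, typical_params):
        dose = DoseEvent(start_time=5.0, amount=100.0, duration=1.0)
        assert conc_single_infusion(typical_params, dose, 5.0) == 0.0
        assert conc_single_infusion(typical_params, dose, 2.0) == 0.0

    def test_mass_conservation_without_elimination(self):
        # CL -> 0: all infused drug stays in the two compartments
        p = IndividualParams(V1=2.31, V2=16.19, Q=0.23, CL=1e-9)
        dose = DoseEvent(start_time=0.0, amount=100.0, duration=1.0)
        t = 5000.0
        c1 = conc_single_infusion(p, dose, t)
        # at equilibrium the peripheral concentration (A2/V2) matches A1/V1
        total = c1 * p.V1 + c1 * p.V2
        assert total == pytest.approx(100.0, rel=1e-3)

    def test_matches_ode_oracle(self, typical_params):
        dose = DoseEvent(start_time=0.0, amount=100.0, duration=1.0)
        times = [0.5, 1.0, 1.5, 6.0, 24.0]
        analytic = np.array([conc_single_infusion(typical_params, dose, t) for t in times])
        oracle = ode_profile(typical_params, [dose], times)
        np.testing.assert_allclose(analytic, oracle, rtol=1e-6)


class TestSimulateProfile:
    REGIMEN = [
        DoseEvent(0.0, 100.0, 1.0),
        DoseEvent(12.0, 100.0, 1.0),
        DoseEvent(24.0, 100.0, 1.0),
        DoseEvent(48.0, 100.0, 1.0),
    ]

    def test_multidose_matches_ode_oracle(self, typical_params):
        times = [1.0, 11.9, 13.0, 30.0, 49.0, 72.0]
        analytic = simulate_profile(typical_params, self.REGIMEN, times)
        oracle = ode_profile(typical_params, self.REGIMEN, times)
        np.testing.assert_allclose(analytic, oracle, rtol=1e-6)

    def test_randomized_params_match_ode(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = IndividualParams(
                V1=rng.uniform(0.5, 5.0),
                V2=rng.uniform(2.0, 40.0),
                Q=rng.uniform(0.05, 1.0),
                CL=rng.uniform(0.02, 0.5),
            )
            doses = [DoseEvent(0.0, rng.uniform(20, 200), rng.uniform(0.5, 2.0))]
            times = sorted(rng.uniform(0.1, 48.0, size=4))
            analytic = simulate_profile(p, doses, times)
            oracle = ode_profile(p, doses, times)
            np.testing.assert_allclose(analytic, oracle, rtol=1e-6, atol=1e-12)

    def test_linearity_in_dose(self, typical_params):
        times = np.linspace(0.0, 72.0, 50)
        base = simulate_profile(typical_params, self.REGIMEN, times)
        doubled = simulate_profile(
            typical_params,
            [DoseEvent(d.start_time, 2 * d.amount, d.duration) for d in self.REGIMEN],
            times,
        )
        np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-12)

    def test_superposition_of_split_doses(self, typical_params):
        times = np.linspace(0.0, 48.0, 30)
        whole = simulate_profile(typical_params, [DoseEvent(0.0, 100.0, 1.0)], times)
        split = simulate_profile(
            typical_params,
            [DoseEvent(0.0, 50.0, 1.0), DoseEvent(0.0, 50.0, 1.0)],
            times,
        )
        np.testing.assert_allclose(split, whole, rtol=1e-12)

    def test_empty_dose_list(self, typical_params):
        out = simulate_profile(typical_params, [], [0.0, 1.0, 2.0])
        assert np.all(out == 0.0)

    def test_non_negative_and_peak_at_infusion_end(self, typical_params):
        dose = DoseEvent(0.0, 100.0, 1.0)
        times = np.linspace(0.0, 48.0, 2000)
        prof = simulate_profile(typical_params, [dose], times)
        assert np.all(prof >= 0.0)
        assert abs(times[np.argmax(prof)] - dose.end_time) < 0.05

    def test_unsorted_times_rejected(self, typical_params):
        with pytest.raises(ValueError):
            simulate_profile(typical_params, self.REGIMEN, [2.0, 1.0])


class TestConcProfiles:
    def test_matches_scalar_path(self, typical_params):
        doses = [DoseEvent(0.0, 80.0, 1.0), DoseEvent(24.0, 120.0, 0.5)]
        times = np.array([0.5, 10.0, 25.0, 47.0])
        single = simulate_profile(typical_params, doses, times)
        batch = conc_profiles(
            typical_params.as_array()[None, :],
            times,
            [d.start_time for d in doses],
            [d.amount for d in doses],
            [d.duration for d in doses],
        )
        np.testing.assert_allclose(batch[0], single, rtol=1e-12)

    def test_per_subject_amounts(self, typical_params):
        times = np.array([3.0, 20.0])
        amounts = np.array([[100.0], [200.0]])
        params = np.vstack([typical_params.as_array()] * 2)
        out = conc_profiles(params, times, [0.0], amounts, [1.0])
        np.testing.assert_allclose(out[1], 2.0 * out[0], rtol=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    v1=st.floats(0.5, 10.0),
    v2=st.floats(1.0, 50.0),
    q=st.floats(0.01, 2.0),
    cl=st.floats(0.01, 1.0),
    scale=st.floats(0.1, 10.0),
)
def test_dose_scaling_property(v1, v2, q, cl, scale):
    p = IndividualParams(V1=v1, V2=v2, Q=q, CL=cl)
    times = np.array([0.5, 2.0, 10.0, 40.0])
    base = simulate_profile(p, [DoseEvent(0.0, 100.0, 1.0)], times)
    scaled = simulate_profile(p, [DoseEvent(0.0, 100.0 * scale, 1.0)], times)
    np.testing.assert_allclose(scaled, scale * base, rtol=1e-9)
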