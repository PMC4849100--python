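"""Binding modulator model: construction, equilibrium, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sampkinetics as sk
from sampkinetics.binding import _two_species_bound

log_param = st.floats(min_value=-2.0, max_value=2.0).map(lambda x: 10.0**x)


class TestKineticsConstruction:
    def test_identity_case(self):
        kin = sk.build_binding_kinetics(alpha=1.0, beta=1.0, K1=1.0)
        assert kin.K1 == kin.K3 == kin.K4 == kin.K5 == 1.0
        assert kin.km1 == kin.km3 == kin.km4 == kin.km5 == 1.0

    def test_dissociation_constants_follow_alpha_beta(self):
        kin = sk.build_binding_kinetics(alpha=10.0, beta=0.1, K1=1.0)
        assert np.isclose(kin.K3, 0.1) and np.isclose(kin.K5, 10.0)
        assert np.isclose(kin.K4, 1.0)
        assert np.isclose(kin.K4 / kin.K3, kin.K5 / kin.K1)

    @given(alpha=log_param, beta=log_param, K1=log_param)
    @settings(max_examples=50, deadline=None)
    def test_detailed_balance_by_construction(self, alpha, beta, K1):
        kin = sk.build_binding_kinetics(alpha=alpha, beta=beta, K1=K1)
        # recompute the cycle from the returned rates only
        lhs = (kin.km4 / kin.k4) / (kin.km3 / kin.k3)
        rhs = (kin.km5 / kin.k5) / (kin.km1 / kin.k1)
        assert abs(lhs - rhs) / lhs < 1e-12
        assert np.isclose(kin.alpha, alpha) and np.isclose(kin.beta, beta)

    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(beta=-1), dict(K1=0)])
    def test_nonpositive_inputs_rejected(self, bad):
        params = dict(alpha=1.0, beta=1.0, K1=1.0)
        params.update(bad)
        with pytest.raises(sk.ParameterError):
            sk.build_binding_kinetics(**params)

    def test_inconsistent_rates_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.BindingKinetics(k1=1, k3=1, k4=1, k5=1, km1=1, km3=1, km4=2, km5=1)


class TestRHS:
    def test_single_active_term(self):
        kin = sk.build_binding_kinetics(alpha=1.0, beta=1.0, K1=1.0)
        ctx = sk.BindingContext(R_T=1.0, M_T=1.0, S_T=0.0)
        d = sk.binding_rhs([0.0, 0.0, 0.0], kin, ctx)
        assert np.allclose(d, [1.0, 0.0, 0.0])  # only k1*[R][M] fires

    def test_totals_conserved_exactly(self, simple_binding):
        ctx = sk.BindingContext(R_T=1.0, M_T=2.0, S_T=0.5)
        d = sk.binding_rhs([0.1, 0.05, 0.2], simple_binding, ctx)
        # d(R + MR + SMR)/dt = -(dMR + dSMR) + (dMR + dSMR) = 0 structurally:
        # the free species are reconstructed from the totals, so the implied
        # free-species derivatives cancel the complex derivatives exactly
        dMR, dSMR, dSM = d
        dR = -(dMR + dSMR)
        dS = -(dSM + dSMR)
        dM = -(dSM + dMR + dSMR)
        assert abs(dR + dMR + dSMR) < 1e-14
        assert abs(dS + dSM + dSMR) < 1e-14
        assert abs(dM + dSM + dMR + dSMR) < 1e-14

    def test_rhs_vanishes_at_equilibrium(self, simple_binding):
        ctx = sk.BindingContext(R_T=1.0, M_T=2.0, S_T=0.7)
        eq = sk.binding_equilibrium(simple_binding, ctx)
        d = sk.binding_rhs([eq.MR, eq.SMR, eq.SM], simple_binding, ctx)
        assert np.max(np.abs(d)) < 1e-9

    def test_inconsistent_state_rejected(self, simple_binding):
        ctx = sk.BindingContext(R_T=1.0, M_T=1.0, S_T=0.0)
        with pytest.raises(sk.StateConsistencyError):
            sk.binding_rhs([2.0, 0.0, 0.0], simple_binding, ctx)


class TestEquilibrium:
    def test_no_ligands_all_free(self, simple_binding):
        eq = sk.binding_equilibrium(
            simple_binding, sk.BindingContext(R_T=1.0, M_T=0.0, S_T=0.0)
        )
        assert eq.R == 1.0 and eq.MR == 0.0

    def test_two_species_quadratic(self):
        kin = sk.build_binding_kinetics(alpha=1.0, beta=1.0, K1=1.0)
        eq = sk.binding_equilibrium(kin, sk.BindingContext(R_T=1.0, M_T=1.0, S_T=0.0))
        assert abs(eq.MR - (3.0 - np.sqrt(5.0)) / 2.0) < 1e-12
        assert abs(eq.R - (np.sqrt(5.0) - 1.0) / 2.0) < 1e-12

    def test_matches_ode_integration(self, rng):
        """Algebraic equilibrium vs. stiff integration of the mass-action ODEs."""
        for _ in range(100):
            alpha, beta, K1, mu = 10.0 ** rng.uniform(-2, 2, size=4)
            kin = sk.build_binding_kinetics(alpha=alpha, beta=beta, K1=K1)
            ctx = sk.BindingContext(R_T=1.0, M_T=mu, S_T=10.0 ** rng.uniform(-2, 2))
            eq = sk.binding_equilibrium(kin, ctx)
            res = sk.integrate_to_steady_state(
                lambda y: sk.binding_rhs(y, kin, ctx, clamp=True), [0.0, 0.0, 0.0]
            )
            assert np.max(np.abs(res.state - [eq.MR, eq.SMR, eq.SM])) < 1e-8

    def test_conservation_at_equilibrium(self, simple_binding):
        ctx = sk.BindingContext(R_T=1.0, M_T=3.0, S_T=2.0)
        eq = sk.binding_equilibrium(simple_binding, ctx)
        assert eq.conservation_report(ctx).ok


class TestClosedForms:
    def test_basal_fraction_limits(self):
        assert sk.basal_free_regulator(0.0, 1.0) == 1.0
        assert abs(sk.basal_free_regulator(1.0, 1.0) - 0.6180339887498949) < 1e-12
        assert sk.basal_free_regulator(1e9, 1.0) < 1e-6

    @pytest.mark.parametrize(
        "alpha,K_R1,mu,expected",
        [
            (1.0, 1.0, 1.0, 0.0),          # no cooperativity, no response
            (10.0, 1.0, 0.0, 0.0),         # no modulator, no response
            (10.0, 1.0, 1.0, 0.2980457943497212),
        ],
    )
    def test_amplitude_values(self, alpha, K_R1, mu, expected):
        assert abs(float(sk.amplitude_binding(alpha, K_R1, mu)) - expected) < 1e-12

    def test_amplitude_matches_equilibrium_endpoints(self, amplitude_oracle):
        for alpha, K1, mu in [(10.0, 1.0, 1.0), (0.1, 0.5, 3.0), (30.0, 2.0, 0.3)]:
            kin = sk.build_binding_kinetics(alpha=alpha, beta=1.0, K1=K1)
            A_num = amplitude_oracle("binding", kin, R_T=1.0, M_T=mu)
            A_cf = float(sk.amplitude_binding(alpha, K1, mu))
            assert abs(A_num - A_cf) < 1e-6

    @given(
        alpha=log_param, K_R1=log_param,
        mu=st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_sign_law_and_bound(self, alpha, K_R1, mu):
        A = float(sk.amplitude_binding(alpha, K_R1, mu))
        assert abs(A) <= 1.0 + 1e-12
        if mu > 1e-9:
            if alpha > 1 + 1e-9:
                assert A > 0
            elif alpha < 1 - 1e-9:
                assert A < 0

    def test_optimal_modulator_concentration(self):
        assert sk.optimal_modulator_concentration(1.0, 1.0, 1.0) == 2.0
        assert abs(
            sk.optimal_modulator_concentration(1.0, 5.0, 50.0) - (1 + np.sqrt(250.0))
        ) < 1e-12
        assert sk.optimal_modulator_concentration(1.0, 1e-12, 1e-12) == pytest.approx(1.0)

    def test_optimum_matches_numeric_argmax(self):
        """M_opt = R_T + sqrt(K1*K5) against a fine scan of the amplitude."""
        R_T, K1, alpha = 1.0, 5.0, 10.0
        M_opt = sk.optimal_modulator_concentration(R_T, K1, alpha * K1)
        mus = np.linspace(0.5, 60.0, 20000) / R_T
        A = sk.amplitude_binding(alpha, K1 / R_T, mus)
        assert abs(mus[np.argmax(A)] * R_T - M_opt) / M_opt < 1e-3
        assert abs(M_opt - 16.811) < 1e-2

    @given(alpha=log_param, K_R1=log_param)
    @settings(max_examples=100, deadline=None)
    def test_amplitude_at_optimum_identity(self, alpha, K_R1):
        mu_opt = float(sk.optimal_mu(alpha, K_R1))
        A_at = float(sk.amplitude_binding(alpha, K_R1, mu_opt))
        assert abs(float(sk.amplitude_at_optimum(alpha, K_R1)) - A_at) < 1e-10

    def test_amplitude_at_optimum_value(self):
        assert abs(float(sk.amplitude_at_optimum(10.0, 5.0)) - 0.513) < 1e-3
        assert float(sk.amplitude_at_optimum(1.0, 5.0)) == 0.0
        assert abs(float(sk.amplitude_at_optimum(10.0, 1e-10))) < 1e-4


def test_two_species_helper_bounds():
    MR = _two_species_bound(1.0, 1.0, 1.0)
    assert 0 <= MR <= 1 and abs(MR - (3 - np.sqrt(5)) / 2) < 1e-14
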