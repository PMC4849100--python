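"""Enzymatic modulator model: construction, steady states, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sampkinetics as sk
from sampkinetics import enzymatic as enz

log_param = st.floats(min_value=-2.0, max_value=2.0).map(lambda x: 10.0**x)


class TestConstruction:
    def test_identity_case(self):
        kin = sk.build_enzymatic_kinetics(
            alpha_E=1.0, alpha_B=1.0, beta_E=1.0, K_M=1.0, kappa=1.0, gamma=0.0
        )
        assert kin.K_M == kin.K_Mp == kin.K3 == kin.K4 == 1.0
        assert kin.k6 == kin.k2

    def test_caption_construction(self):
        """Unit reference rates with fixed k1 = k3 = 1/(uM s)."""
        for aE, aB in [(10.0, 0.1), (0.1, 10.0)]:
            kin = sk.build_caption_kinetics(alpha_E=aE, alpha_B=aB, kappa=1.0, gamma=1.0)
            assert kin.K_M == 2.0
            assert kin.K3 == 1.0
            assert np.isclose(kin.K_Mp, 2.0 * aB)
            assert np.isclose(kin.k6, aE)
            assert np.isclose(kin.k5, (1.0 + aE) / (2.0 * aB))
            assert np.isclose(kin.K4, 1.0 / aB)
            assert np.isclose(kin.k4, aB)

    @given(aE=log_param, aB=log_param, bE=log_param, K_M=log_param)
    @settings(max_examples=50, deadline=None)
    def test_cycle_constraint_by_construction(self, aE, aB, bE, K_M):
        kin = sk.build_enzymatic_kinetics(
            alpha_E=aE, alpha_B=aB, beta_E=bE, K_M=K_M, kappa=1.0, gamma=0.1
        )
        lhs = (kin.km3 / kin.k3) * ((kin.km1 + kin.k2) / kin.k1)
        rhs = (kin.km4 / kin.k4) * ((kin.km5 + kin.k6) / kin.k5)
        assert abs(lhs - rhs) / lhs < 1e-12
        assert np.isclose(kin.alpha_E, aE)
        assert np.isclose(kin.alpha_B, aB)
        assert np.isclose(kin.beta_E, bE)

    def test_binding_limit_alpha_B_equals_alpha(self):
        """With catalysis off, the binding cooperativity is K'_M/K_M = k-5*k1/(k5*k-1)."""
        kin = sk.build_enzymatic_kinetics(
            alpha_E=2.0, alpha_B=7.0, beta_E=1.0, K_M=1.0, kappa=1.0
        )
        limit = sk.binding_limit_kinetics(kin)
        assert limit.k2 == limit.k6 == limit.gamma == 0.0
        alpha_bind = (limit.km5 / limit.k5) / (limit.km1 / limit.k1)
        assert np.isclose(limit.alpha_B, alpha_bind)
        with pytest.raises(sk.ParameterError):
            limit.alpha_E  # undefined for a pure binder

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.build_enzymatic_kinetics(
                alpha_E=1.0, alpha_B=0.0, beta_E=1.0, K_M=1.0, kappa=1.0
            )
        with pytest.raises(sk.ParameterError):
            sk.build_enzymatic_kinetics(
                alpha_E=1.0, alpha_B=1.0, beta_E=1.0, K_M=1.0, kappa=1.0, k2=0.0
            )


class TestSteadyState:
    def test_no_modulator_active_fraction(self):
        kin = sk.build_enzymatic_kinetics(
            alpha_E=0.5, alpha_B=2.0, beta_E=1.0, K_M=1.0, kappa=2.0, gamma=1.0
        )
        ctx = sk.EnzymaticContext(R_T=3.0, M_T=0.0, S_T=1.0)
        st_ = sk.enzymatic_steady_state(kin, ctx)
        assert abs(st_.Rp - ctx.kappa_r(kin) * ctx.R_T) < 1e-9

    def test_symmetric_cycle_half_active(self):
        """kappa = gamma and no modulator: half of the regulator is active."""
        kin = sk.build_enzymatic_kinetics(
            alpha_E=1.0, alpha_B=1.0, beta_E=1.0, K_M=1.0, kappa=1.0, gamma=1.0
        )
        st_ = sk.enzymatic_steady_state(kin, sk.EnzymaticContext(R_T=1.0, M_T=0.0))
        assert abs(st_.Rp - 0.5) < 1e-10

    def test_rhs_vanishes_at_steady_state(self):
        kin = sk.build_caption_kinetics(alpha_E=0.1, alpha_B=10.0, kappa=1.0, gamma=1.0)
        ctx = sk.EnzymaticContext(R_T=10.0, M_T=3.0, S_T=2.0)
        st_ = sk.enzymatic_steady_state(kin, ctx)
        d = sk.enzymatic_rhs([st_.MRp, st_.SMRp, st_.SM, st_.Rp], kin, ctx)
        assert np.max(np.abs(d)) < 1e-9

    def test_quasi_equilibrium_relations_hold(self):
        """The ODE steady state satisfies the four steady-state ratios."""
        kin = sk.build_caption_kinetics(alpha_E=10.0, alpha_B=0.1, kappa=1.0, gamma=1.0)
        ctx = sk.EnzymaticContext(R_T=10.0, M_T=3.0, S_T=1.5)
        s = sk.enzymatic_steady_state(kin, ctx)
        assert abs(s.Rp * s.M / s.MRp / kin.K_M - 1) < 1e-8
        assert abs(s.S * s.MRp / s.SMRp / kin.K3 - 1) < 1e-8
        assert abs(s.Rp * s.SM / s.SMRp / kin.K_Mp - 1) < 1e-8
        assert abs(s.S * s.M / s.SM / kin.K4 - 1) < 1e-8

    def test_integration_matches_algebraic_reduction(self, rng):
        for _ in range(30):
            aE, aB, bE, K_M = 10.0 ** rng.uniform(-1.5, 1.5, size=4)
            kin = sk.build_enzymatic_kinetics(
                alpha_E=aE, alpha_B=aB, beta_E=bE, K_M=K_M,
                kappa=10.0 ** rng.uniform(-1, 1), gamma=10.0 ** rng.uniform(-2, 0),
            )
            ctx = sk.EnzymaticContext(
                R_T=1.0, M_T=10.0 ** rng.uniform(-1, 1),
                S_T=10.0 ** rng.uniform(-1, 1),
            )
            a = sk.enzymatic_steady_state(kin, ctx, method="integrate")
            b = sk.enzymatic_steady_state(kin, ctx, method="algebraic")
            for f in ("M", "R", "Rp", "S", "MRp", "SM", "SMRp"):
                assert abs(getattr(a, f) - getattr(b, f)) < 1e-8

    def test_independent_of_initial_condition(self, rng):
        kin = sk.build_caption_kinetics(alpha_E=0.1, alpha_B=10.0, kappa=1.0, gamma=1.0)
        ctx = sk.EnzymaticContext(R_T=10.0, M_T=7.0, S_T=3.0)
        states = []
        for _ in range(3):
            c = rng.uniform(0, 0.5, size=3)  # small random complex seed
            y0 = [c[0], c[1], c[2], rng.uniform(0, 2.0)]
            res = sk.integrate_to_steady_state(
                lambda y: sk.enzymatic_rhs(y, kin, ctx, clamp=True), y0
            )
            states.append(res.state)
        for s in states[1:]:
            assert np.max(np.abs(s - states[0])) < 1e-7


class TestClosedForms:
    def test_basal_recovers_kappa_r_without_modulator(self):
        assert float(sk.basal_active_regulator(1.0, 0.0, 1.0, 0.7)) == pytest.approx(0.7)

    @given(
        aB=log_param, aE=log_param, K_r=log_param, mu=log_param, iota=log_param,
        kr=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_amplitude_is_plateau_minus_basal(self, aB, aE, K_r, mu, iota, kr):
        basal = float(sk.basal_active_regulator(K_r, mu, iota, kr))
        plateau = float(sk.saturated_active_regulator(aB, aE, K_r, mu, iota, kr))
        A = float(sk.amplitude_enzymatic(aB, aE, K_r, mu, iota, kr))
        # algebraic identity; float cancellation scales with the term sizes
        scale = 1.0 + aB * K_r + max(1.0, aE) * mu * iota
        assert abs((plateau - basal) - A) < 1e-12 * scale

    @pytest.mark.parametrize(
        "aB,aE,expected",
        [(1.0, 1.0, 0.0), (10.0, 0.1, 0.24816197192923628)],
    )
    def test_amplitude_reference_values(self, aB, aE, expected):
        A = float(sk.amplitude_enzymatic(aB, aE, 1.0, 1.0, 1.0, 0.5))
        assert abs(A - expected) < 1e-12

    def test_amplitude_zero_without_modulator(self):
        assert float(sk.amplitude_enzymatic(10.0, 0.1, 1.0, 0.0, 1.0, 0.5)) == 0.0

    def test_basal_matches_steady_state(self):
        kin = sk.build_caption_kinetics(alpha_E=0.1, alpha_B=10.0, kappa=1.0, gamma=1.0)
        for M_T in (0.5, 3.0, 20.0):
            ctx = sk.EnzymaticContext(R_T=10.0, M_T=M_T)
            st_ = sk.enzymatic_steady_state(kin, ctx)
            cf = float(
                sk.basal_active_regulator(
                    ctx.K_r(kin), ctx.mu, ctx.iota(kin), ctx.kappa_r(kin)
                )
            )
            assert abs(st_.Rp / ctx.R_T - cf) / cf < 1e-6


class TestOptimalMu:
    def test_reference_value(self):
        assert float(
            sk.optimal_mu_binding_only(4.0, 1.0, k2=1.0, kappa=1.0, gamma=1.0)
        ) == pytest.approx(2.5)

    def test_saturates_at_binding_optimum(self):
        mu_B = 1.0 + 1.0 * np.sqrt(4.0)
        val = float(sk.optimal_mu_binding_only(4.0, 1.0, k2=1.0, kappa=1e6, gamma=1.0))
        assert abs(val - mu_B) / mu_B < 1e-5

    def test_strong_catalysis_needs_little_modulator(self):
        assert float(
            sk.optimal_mu_binding_only(4.0, 1.0, k2=1e6, kappa=1.0, gamma=1.0)
        ) < 1e-4

    def test_matches_numeric_argmax(self):
        """Closed-form optimum vs. a fine scan of the amplitude (alpha_E = 1)."""
        aB, K_r, k2, kappa, gamma = 4.0, 1.0, 1.0, 1.0, 1.0
        iota, kr = k2 / (gamma + kappa), kappa / (gamma + kappa)
        mus = np.linspace(0.01, 20.0, 40000)
        A = sk.amplitude_enzymatic(aB, 1.0, K_r, mus, iota, kr)
        mu_num = mus[np.argmax(A)]
        mu_cf = float(sk.optimal_mu_binding_only(aB, K_r, k2, kappa, gamma))
        assert abs(mu_num - mu_cf) / mu_cf < 5e-3


class TestBindingLimit:
    def test_reproduces_binding_dose_response(self, rng):
        """k2 = k6 = 0, gamma = 0: the active regulator follows the binding model."""
        for _ in range(5):
            aB, bE, K_M = 10.0 ** rng.uniform(-1, 1, size=3)
            ekin = sk.binding_limit_kinetics(
                sk.build_enzymatic_kinetics(
                    alpha_E=1.0, alpha_B=aB, beta_E=bE, K_M=K_M, kappa=1.0
                )
            )
            # with catalysis off: K1 -> K_M = k-1/k1, K5 -> K'_M = k-5/k5;
            # the S constants swap roles between the two parameterizations
            bkin = sk.BindingKinetics(
                k1=ekin.k1, km1=ekin.km1, k5=ekin.k5, km5=ekin.km5,
                k3=ekin.k4, km3=ekin.km4, k4=ekin.k3, km4=ekin.km3,
            )
            R_T, M_T = 1.0, float(10.0 ** rng.uniform(-0.5, 0.5))
            for S_T in np.logspace(-2, 2, 7):
                ectx = sk.EnzymaticContext(R_T=R_T, M_T=M_T, S_T=S_T)
                bctx = sk.BindingContext(R_T=R_T, M_T=M_T, S_T=S_T)
                es = sk.enzymatic_steady_state(ekin, ectx, method="integrate")
                bs = sk.binding_equilibrium(bkin, bctx)
                assert abs(es.Rp - bs.R) < 1e-6
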