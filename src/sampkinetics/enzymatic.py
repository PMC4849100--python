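"""Enzymatic modulator model.

An enzymatic modulator M (a Rap-phosphatase-like receptor) binds the active
form R' of a response regulator and catalyzes its deactivation; a signaling
peptide S binds at a distinct allosteric site.  The regulator cycles between
inactive R and active R' via a lumped activation rate κ (upstream kinase)
and an intrinsic deactivation rate γ:

    M + R'  ⇌ MR'    (k1 / k-1),   MR'  --k2-->  M + R
    M + S   ⇌ SM     (k4 / k-4)
    MR' + S ⇌ SMR'   (k3 / k-3)
    SM + R' ⇌ SMR'   (k5 / k-5),   SMR' --k6--> SM + R
    R --κ--> R',  R' --γ--> R

Note the rate naming: k3/k-3 govern signal binding to the modulator-regulator
complex and k4/k-4 signal binding to the free modulator (the roles the
steady-state constants K3 and K4 play below).  Catalysis in the ternary
complex releases the deactivated regulator while the signal remains bound,
i.e. SMR' → SM + R; with this routing the steady state of the full ODE
system satisfies the quasi-equilibrium relations exactly:

    [R'][M]/[MR']   = (k-1 + k2)/k1 = K_M
    [S][MR']/[SMR'] = k-3/k3        = K3
    [R'][SM]/[SMR'] = (k-5 + k6)/k5 = K'_M
    [S][M]/[SM]     = k-4/k4        = K4

with the thermodynamic-cycle constraint K3·K_M = K4·K'_M.

Class I parameters: the enzymatic cooperativity alpha_E = k6/k2, the binding
cooperativity alpha_B = K'_M/K_M, and the relative site affinity
beta_E = K4/K_M (the cycle-consistent analogue of the binding model's beta;
K3 then follows from the cycle constraint).  Class II parameters: mu =
M_T/R_T, K_r = K_M/R_T, iota = k2/(γ+κ) and kappa_r = κ/(γ+κ), the active
fraction of the regulator in the absence of modulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .binding import ParameterError, StateConsistencyError, _CLIP
from .numerics import (
    DEFAULT_SETTINGS,
    SolverSettings,
    SteadyStateError,
    SteadyStateResult,
    integrate_to_steady_state,
    verify_conservation,
)

_DB_TOL = 1e-10


@dataclass(frozen=True)
class EnzymaticKinetics:
    """Rate constants of the enzymatic modulator network.

    Association rates ``k1`` (M+R'), ``k4`` (M+S), ``k3`` (MR'+S), ``k5``
    (SM+R') in μM⁻¹ s⁻¹; dissociation rates ``km1``, ``km3``, ``km4``,
    ``km5`` in s⁻¹; catalytic deactivation rates ``k2`` (from MR') and
    ``k6`` (from SMR'); activation rate ``kappa`` and intrinsic deactivation
    rate ``gamma`` in s⁻¹.
    """

    k1: float
    km1: float
    k2: float
    k3: float
    km3: float
    k4: float
    km4: float
    k5: float
    km5: float
    k6: float
    kappa: float
    gamma: float

    def __post_init__(self):
        for name in ("k1", "km1", "k3", "km3", "k4", "km4", "k5", "km5", "kappa"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"rate {name} must be strictly positive")
        for name in ("k2", "k6", "gamma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"rate {name} must be non-negative")
        lhs, rhs = self.K3 * self.K_M, self.K4 * self.K_Mp
        if abs(lhs - rhs) / lhs > _DB_TOL:
            raise ParameterError(
                f"thermodynamic cycle violated: K3·K_M={lhs:.12g} != K4·K'_M={rhs:.12g}"
            )

    @property
    def K_M(self) -> float:
        """Michaelis constant of the unstimulated modulator, (k-1+k2)/k1."""
        return (self.km1 + self.k2) / self.k1

    @property
    def K_Mp(self) -> float:
        """Michaelis constant of the signal-bound modulator, (k-5+k6)/k5."""
        return (self.km5 + self.k6) / self.k5

    @property
    def K3(self) -> float:
        return self.km3 / self.k3

    @property
    def K4(self) -> float:
        return self.km4 / self.k4

    @property
    def alpha_E(self) -> float:
        """Enzymatic cooperativity k6/k2 (undefined for a pure binder)."""
        if self.k2 == 0:
            raise ParameterError("alpha_E is undefined when k2 = 0")
        return self.k6 / self.k2

    @property
    def alpha_B(self) -> float:
        """Binding cooperativity K'_M/K_M."""
        return self.K_Mp / self.K_M

    @property
    def beta_E(self) -> float:
        """Relative site affinity K4/K_M."""
        return self.K4 / self.K_M


@dataclass(frozen=True)
class EnzymaticContext:
    """Total concentrations (μM); Class II parameters derive from kinetics."""

    R_T: float
    M_T: float
    S_T: float = 0.0

    def __post_init__(self):
        if not self.R_T > 0:
            raise ParameterError("R_T must be strictly positive")
        if self.M_T < 0 or self.S_T < 0:
            raise ParameterError("M_T and S_T must be non-negative")

    @property
    def mu(self) -> float:
        return self.M_T / self.R_T

    def K_r(self, kinetics: EnzymaticKinetics) -> float:
        return kinetics.K_M / self.R_T

    def iota(self, kinetics: EnzymaticKinetics) -> float:
        """Relative enzymatic inactivation rate k2/(γ+κ)."""
        return kinetics.k2 / (kinetics.gamma + kinetics.kappa)

    def kappa_r(self, kinetics: EnzymaticKinetics) -> float:
        """Modulator-free active fraction κ/(γ+κ)."""
        return kinetics.kappa / (kinetics.gamma + kinetics.kappa)


@dataclass(frozen=True)
class EnzymaticState:
    """Species concentrations (μM); R is the inactive, R' the active form."""

    M: float
    R: float
    Rp: float
    S: float
    MRp: float
    SM: float
    SMRp: float

    def conservation_report(self, context: EnzymaticContext, tol: float = 1e-9):
        sums = {
            "R_T": self.R + self.Rp + self.MRp + self.SMRp,
            "S_T": self.S + self.SM + self.SMRp,
            "M_T": self.M + self.SM + self.MRp + self.SMRp,
        }
        totals = {"R_T": context.R_T, "S_T": context.S_T, "M_T": context.M_T}
        return verify_conservation(sums, totals, tol)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_enzymatic_kinetics(
    alpha_E: float,
    alpha_B: float,
    beta_E: float,
    K_M: float,
    kappa: float,
    gamma: float = 0.0,
    k2: float = 1.0,
    dissociation_rates: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> EnzymaticKinetics:
    """Build a cycle-consistent rate set from the allosteric parameters.

    The dissociation rates ``(k-1, k-3, k-4, k-5)`` and ``k2`` are the fixed
    references; the association rates and ``k6`` are derived:
    k6 = alpha_E·k2, k1 = (k-1+k2)/K_M, K'_M = alpha_B·K_M hence
    k5 = (k-5+k6)/K'_M, K4 = beta_E·K_M hence k4 = k-4/K4, and
    K3 = K4·K'_M/K_M closes the cycle, hence k3 = k-3/K3.
    """
    if not (alpha_B > 0 and beta_E > 0 and K_M > 0 and kappa > 0 and k2 > 0):
        raise ParameterError(
            "alpha_B, beta_E, K_M, kappa and k2 must be strictly positive"
        )
    if alpha_E < 0 or gamma < 0:
        raise ParameterError("alpha_E and gamma must be non-negative")
    km1, km3, km4, km5 = dissociation_rates
    if not all(k > 0 for k in dissociation_rates):
        raise ParameterError("dissociation rates must be strictly positive")
    k6 = alpha_E * k2
    k1 = (km1 + k2) / K_M
    K_Mp = alpha_B * K_M
    k5 = (km5 + k6) / K_Mp
    K4 = beta_E * K_M
    K3 = K4 * K_Mp / K_M
    return EnzymaticKinetics(
        k1=k1, km1=km1, k2=k2, k3=km3 / K3, km3=km3, k4=km4 / K4, km4=km4,
        k5=k5, km5=km5, k6=k6, kappa=kappa, gamma=gamma,
    )


def build_caption_kinetics(
    alpha_E: float,
    alpha_B: float,
    kappa: float,
    gamma: float,
    beta_E: float | None = None,
    k2: float = 1.0,
    km1: float = 1.0,
    km3: float = 1.0,
    km4: float = 1.0,
    km5: float = 1.0,
    k1: float = 1.0,
    k3: float = 1.0,
) -> EnzymaticKinetics:
    """Build rates the way the dose-response figure setups fix them.

    Here ``k1`` and ``k3`` are fixed (1 μM⁻¹ s⁻¹) alongside the unit
    dissociation rates, and (k4, k5, k6) are derived from the allosteric
    parameters plus the cycle constraint.  With ``beta_E`` given, ``k-3`` is
    derived instead of fixed (the design-space setup), so K3 = beta_E·
    alpha_B·K_M; otherwise K3 = k-3/k3 stays at its fixed value and beta_E
    is implied.
    """
    if not (alpha_B > 0 and kappa > 0 and k2 > 0):
        raise ParameterError("alpha_B, kappa and k2 must be strictly positive")
    k6 = alpha_E * k2
    K_M = (km1 + k2) / k1
    K_Mp = alpha_B * K_M
    k5 = (km5 + k6) / K_Mp
    if beta_E is not None:
        K4 = beta_E * K_M
        K3 = K4 * K_Mp / K_M
        km3 = K3 * k3
    else:
        K3 = km3 / k3
        K4 = K3 * K_M / K_Mp
    return EnzymaticKinetics(
        k1=k1, km1=km1, k2=k2, k3=k3, km3=km3, k4=km4 / K4, km4=km4,
        k5=k5, km5=km5, k6=k6, kappa=kappa, gamma=gamma,
    )


def binding_limit_kinetics(
    kinetics: EnzymaticKinetics,
) -> EnzymaticKinetics:
    """The pure-binding configuration: k2 = k6 = 0 and γ = 0.

    The catalytic losses are absorbed into the dissociation rates
    (k-1 → k-1 + k2, k-5 → k-5 + k6) so that K_M and K'_M — and with them
    the thermodynamic cycle — are preserved.  With catalysis off and no
    intrinsic deactivation, all regulator is active at steady state and the
    network reduces to the binding modulator model with K1 → K_M and
    K5 → K'_M.
    """
    return EnzymaticKinetics(
        k1=kinetics.k1, km1=kinetics.km1 + kinetics.k2, k2=0.0,
        k3=kinetics.k3, km3=kinetics.km3,
        k4=kinetics.k4, km4=kinetics.km4,
        k5=kinetics.k5, km5=kinetics.km5 + kinetics.k6, k6=0.0,
        kappa=kinetics.kappa, gamma=0.0,
    )


# ---------------------------------------------------------------------------
# ODE right-hand side and steady state
# ---------------------------------------------------------------------------

def _free_species(MRp, SMRp, SM, Rp, context: EnzymaticContext, clamp: bool = False):
    S = context.S_T - SM - SMRp
    M = context.M_T - SM - MRp - SMRp
    R = context.R_T - Rp - MRp - SMRp
    if clamp:
        # smooth extension (see binding._free_species): keeps the vector
        # field differentiable so the Newton polish is regular even when the
        # steady state sits on the feasibility boundary (e.g. free R = 0 in
        # the pure-binding limit)
        return M, R, S
    out = []
    scale = max(context.R_T, context.M_T, context.S_T, 1.0)
    for x in (M, R, S):
        if x < -_CLIP * scale:
            raise StateConsistencyError(
                f"state exceeds conserved totals (free species {x:.3e} μM)"
            )
        out.append(max(x, 0.0))
    return tuple(out)


def enzymatic_rhs(
    state, kinetics: EnzymaticKinetics, context: EnzymaticContext,
    clamp: bool = False,
) -> np.ndarray:
    """Time derivatives d([MR'], [SMR'], [SM], [R'])/dt under mass action.

    Free [M], [S] and inactive [R] are reconstructed from the totals, so all
    three conservation relations hold exactly along any trajectory.  With
    ``clamp=True`` infeasible inputs are projected onto the feasible region
    instead of raising (used during stiff integration, whose trial steps may
    transiently overshoot the totals).
    """
    MRp, SMRp, SM, Rp = state
    M, R, S = _free_species(MRp, SMRp, SM, Rp, context, clamp=clamp)
    k = kinetics
    dMRp = -(k.km1 + k.k2 + k.k3 * S) * MRp + k.k1 * Rp * M + k.km3 * SMRp
    dSMRp = -(k.km5 + k.km3 + k.k6) * SMRp + k.k5 * SM * Rp + k.k3 * S * MRp
    dSM = -(k.km4 + k.k5 * Rp) * SM + k.k4 * S * M + (k.km5 + k.k6) * SMRp
    dRp = (
        -(k.k1 * M + k.k5 * SM) * Rp
        + k.km1 * MRp
        + k.km5 * SMRp
        + k.kappa * R
        - k.gamma * Rp
    )
    return np.array([dMRp, dSMRp, dSM, dRp])


def _state_from_vector(y, context) -> EnzymaticState:
    MRp, SMRp, SM, Rp = y
    M, R, S = _free_species(MRp, SMRp, SM, Rp, context)
    return EnzymaticState(M=M, R=R, Rp=Rp, S=S, MRp=MRp, SM=SM, SMRp=SMRp)


def _algebraic_steady_state(
    kinetics: EnzymaticKinetics, context: EnzymaticContext
) -> EnzymaticState:
    """Semi-analytic reduction: quasi-equilibria + flux balance + totals.

    Unknowns are the free concentrations (M, R', S); complexes follow from
    the quasi-equilibrium relations and the inactive pool from the
    activation/deactivation flux balance κ[R] = γ[R'] + k2[MR'] + k6[SMR'].
    """
    k = kinetics
    K_M, K3, K4 = k.K_M, k.K3, k.K4
    R_T, M_T, S_T = context.R_T, context.M_T, context.S_T
    kr = context.kappa_r(kinetics)

    if M_T == 0.0:
        return EnzymaticState(
            M=0.0, R=(1 - kr) * R_T, Rp=kr * R_T, S=S_T, MRp=0.0, SM=0.0, SMRp=0.0
        )

    with_signal = S_T > 0.0

    def unpack(logx):
        if with_signal:
            M, Rp, S = np.exp(logx)
        else:
            M, Rp = np.exp(logx)
            S = 0.0
        MRp = M * Rp / K_M
        SMRp = S * MRp / K3
        SM = S * M / K4
        R = (k.gamma * Rp + k.k2 * MRp + k.k6 * SMRp) / k.kappa
        return M, Rp, S, MRp, SMRp, SM, R

    def residual(logx):
        M, Rp, S, MRp, SMRp, SM, R = unpack(logx)
        res = [
            (R + Rp + MRp + SMRp) / R_T - 1.0,
            (M + SM + MRp + SMRp) / M_T - 1.0,
        ]
        if with_signal:
            res.append((S + SM + SMRp) / S_T - 1.0)
        return np.array(res)

    guess = [min(M_T, 0.5 * K_M + M_T * 0.5), kr * R_T * 0.5 + 1e-9]
    if with_signal:
        guess.append(S_T * 0.5)
    sol = root(residual, np.log(guess), method="hybr", tol=1e-13)
    if np.max(np.abs(residual(sol.x))) > 1e-9:
        raise SteadyStateError(
            "semi-analytic steady state did not converge",
            float(np.max(np.abs(residual(sol.x)))),
        )
    M, Rp, S, MRp, SMRp, SM, R = unpack(sol.x)
    return EnzymaticState(M=M, R=R, Rp=Rp, S=S, MRp=MRp, SM=SM, SMRp=SMRp)


def enzymatic_steady_state(
    kinetics: EnzymaticKinetics,
    context: EnzymaticContext,
    settings: SolverSettings = DEFAULT_SETTINGS,
    method: str = "integrate",
) -> EnzymaticState:
    """Steady state of the enzymatic network.

    ``method="integrate"`` (default) integrates the stiff ODEs to quiescence
    and Newton-polishes the root; ``method="algebraic"`` solves the
    semi-analytic reduction (quasi-equilibria, flux balance, conservation)
    directly.  The two agree to solver tolerance and are cross-checked in
    the test suite.  Conservation is verified at 1e-9 relative on return.
    """
    if method == "algebraic":
        state = _algebraic_steady_state(kinetics, context)
    elif method == "integrate":
        if kinetics.gamma == 0.0 and kinetics.k2 == 0.0 and kinetics.k6 == 0.0:
            # no deactivation channel at all: R drains fully into the active
            # pool; start there so the integrator does not crawl through the
            # slow κ-limited transient
            y0 = [0.0, 0.0, 0.0, context.R_T]
        else:
            y0 = [0.0, 0.0, 0.0, context.kappa_r(kinetics) * context.R_T]
        # at saturating S_T the Jacobian norm ~ k·S_T is huge; scale the
        # residual criterion so it bounds the state error, not the raw rate
        k = kinetics
        scale = 1.0 + max(k.k1, k.k3, k.k4, k.k5) * max(
            context.R_T, context.M_T, context.S_T
        )
        result = integrate_to_steady_state(
            lambda y: enzymatic_rhs(y, kinetics, context, clamp=True), y0, settings,
            residual_scale=scale,
        )
        state = _state_from_vector(result.state, context)
    else:
        raise ValueError(f"unknown method {method!r}")
    report = state.conservation_report(context)
    if not report.ok:
        raise SteadyStateError(f"steady state violates conservation: {report.residuals}")
    return state


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def basal_active_regulator(K_r, mu, iota, kappa_r):
    """Active-regulator fraction [R']/R_T at zero signal.

    ½·(κ_r(1−μ) − K_r − μι + sqrt(4·K_r·κ_r + (K_r + μι + κ_r(μ−1))²)).
    The saturated plateau is the same expression with K_r → alpha_B·K_r and
    ι → alpha_E·ι; their difference is the closed-form amplitude.
    Accepts arrays.
    """
    K_r = np.asarray(K_r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    iota = np.asarray(iota, dtype=float)
    kappa_r = np.asarray(kappa_r, dtype=float)
    if np.any(K_r <= 0) or np.any(kappa_r <= 0) or np.any(mu < 0) or np.any(iota < 0):
        raise ParameterError("require K_r, kappa_r > 0 and mu, iota >= 0")
    q = K_r + mu * iota + kappa_r * (mu - 1.0)
    return 0.5 * (
        kappa_r * (1.0 - mu) - K_r - mu * iota
        + np.sqrt(4.0 * K_r * kappa_r + q * q)
    )


def saturated_active_regulator(alpha_B, alpha_E, K_r, mu, iota, kappa_r):
    """Active-regulator fraction [R']/R_T at saturating signal."""
    return basal_active_regulator(
        np.asarray(alpha_B, float) * np.asarray(K_r, float),
        mu,
        np.asarray(alpha_E, float) * np.asarray(iota, float),
        kappa_r,
    )


def amplitude_enzymatic(alpha_B, alpha_E, K_r, mu, iota, kappa_r):
    """Relative response amplitude A of an enzymatic modulator.

    A = ½·(K_r(1−α_B) + μι(1−α_E)
          − sqrt(4·K_r·κ_r + (K_r + μι + κ_r(μ−1))²)
          + sqrt(4·α_B·K_r·κ_r + (α_B·K_r + α_E·μι + κ_r(μ−1))²))

    Both cooperativities now shape the sign: for coherent modulators
    (alpha_B > 1 with alpha_E < 1, or vice versa) the sign is fixed across
    all contexts; incoherent modulators can switch sign with context.
    Accepts arrays.
    """
    alpha_B = np.asarray(alpha_B, dtype=float)
    alpha_E = np.asarray(alpha_E, dtype=float)
    K_r = np.asarray(K_r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    iota = np.asarray(iota, dtype=float)
    kappa_r = np.asarray(kappa_r, dtype=float)
    if np.any(K_r <= 0) or np.any(kappa_r <= 0):
        raise ParameterError("require K_r > 0 and kappa_r > 0")
    if np.any(alpha_B <= 0) or np.any(alpha_E < 0) or np.any(mu < 0) or np.any(iota < 0):
        raise ParameterError("require alpha_B > 0 and alpha_E, mu, iota >= 0")
    q0 = K_r + mu * iota + kappa_r * (mu - 1.0)
    q1 = alpha_B * K_r + alpha_E * mu * iota + kappa_r * (mu - 1.0)
    return 0.5 * (
        K_r * (1.0 - alpha_B)
        + mu * iota * (1.0 - alpha_E)
        - np.sqrt(4.0 * K_r * kappa_r + q0 * q0)
        + np.sqrt(4.0 * alpha_B * K_r * kappa_r + q1 * q1)
    )


def optimal_mu_binding_only(alpha_B, K_r, k2, kappa, gamma):
    """Amplitude-optimal μ for a binding-allostery-only enzyme (alpha_E = 1).

    μ_opt = (1/(1 + k2/κ))·(μ_opt,B + (γ/κ)·(μ_opt,B − 1)) with
    μ_opt,B = 1 + K_r·sqrt(α_B), the binding-modulator optimum.  As κ/γ and
    κ/k2 grow, μ_opt saturates at μ_opt,B; a strongly catalytic modulator
    (k2 ≫ κ) needs far less protein than a binding modulator would.
    """
    alpha_B = np.asarray(alpha_B, dtype=float)
    K_r = np.asarray(K_r, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(alpha_B <= 0) or np.any(K_r <= 0) or np.any(kappa <= 0):
        raise ParameterError("require alpha_B, K_r, kappa > 0")
    if np.any(k2 < 0) or np.any(gamma < 0):
        raise ParameterError("require k2, gamma >= 0")
    mu_opt_B = 1.0 + K_r * np.sqrt(alpha_B)
    return (mu_opt_B + (gamma / kappa) * (mu_opt_B - 1.0)) / (1.0 + k2 / kappa)
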