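"""Binding (sequestration) modulator model.

A monomeric modulator protein M carries two distinct effector sites: one for
a response regulator R and one (allosteric) for a signaling peptide S.  The
reversible reaction network

    M + R  ⇌ MR    (K1)        M + S  ⇌ SM    (K3)
    MR + S ⇌ SMR   (K4)        SM + R ⇌ SMR   (K5)

forms a thermodynamic cycle, so detailed balance forces K4/K3 = K5/K1.  The
modulator sequesters the regulator; the cellular output is the free-regulator
concentration [R] at steady state as a function of total signal [S_T].

Class I (molecular) parameters: the cooperativity alpha = K4/K3 = K5/K1
(alpha > 1: signal and regulator binding mutually inhibitory, the signal
frees the regulator and acts as an inverse agonist; alpha < 1: mutual
enhancement, the signal is an agonist) and beta = K3/K1 = K4/K5 (relative
affinity of the two sites).  Class II (context) parameters: mu = M_T/R_T and
K_R1 = K1/R_T.

Closed forms implemented here: the relative response amplitude A(alpha,
K_R1, mu), the amplitude-maximizing modulator concentration
M_opt = R_T + sqrt(K1·K5), and the amplitude at that optimum A_opt(alpha,
K_R1).  All are validated against the mass-action equilibrium in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .numerics import (
    DEFAULT_SETTINGS,
    SolverSettings,
    SteadyStateError,
    verify_conservation,
)

_DB_TOL = 1e-10  # relative slack on the detailed-balance cycle


class ParameterError(ValueError):
    """A kinetic or context parameter is outside its physical domain."""


class StateConsistencyError(ValueError):
    """A state vector is incompatible with the conserved totals."""


@dataclass(frozen=True)
class BindingKinetics:
    """Mass-action rate constants of the binding modulator network.

    Association rates (μM⁻¹ s⁻¹): ``k1`` (M+R), ``k3`` (M+S), ``k4`` (MR+S),
    ``k5`` (SM+R).  Dissociation rates (s⁻¹): ``km1``, ``km3``, ``km4``,
    ``km5``.  Dissociation constants K_i = k_-i/k_i must close the
    thermodynamic cycle: K4/K3 = K5/K1.
    """

    k1: float
    k3: float
    k4: float
    k5: float
    km1: float
    km3: float
    km4: float
    km5: float

    def __post_init__(self):
        for name in ("k1", "k3", "k4", "k5", "km1", "km3", "km4", "km5"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"rate {name} must be strictly positive")
        lhs, rhs = self.K4 / self.K3, self.K5 / self.K1
        if abs(lhs - rhs) / lhs > _DB_TOL:
            raise ParameterError(
                f"detailed balance violated: K4/K3={lhs:.12g} != K5/K1={rhs:.12g}"
            )

    @property
    def K1(self) -> float:
        return self.km1 / self.k1

    @property
    def K3(self) -> float:
        return self.km3 / self.k3

    @property
    def K4(self) -> float:
        return self.km4 / self.k4

    @property
    def K5(self) -> float:
        return self.km5 / self.k5

    @property
    def alpha(self) -> float:
        """Binding cooperativity K4/K3 = K5/K1."""
        return self.K5 / self.K1

    @property
    def beta(self) -> float:
        """Relative site affinity K3/K1 = K4/K5."""
        return self.K3 / self.K1


@dataclass(frozen=True)
class BindingContext:
    """Signaling-context (Class II) quantities: total concentrations in μM."""

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
        """Relative modulator concentration M_T/R_T."""
        return self.M_T / self.R_T

    def K_R1(self, kinetics: BindingKinetics) -> float:
        """Relative regulator dissociation constant K1/R_T."""
        return kinetics.K1 / self.R_T


@dataclass(frozen=True)
class BindingState:
    """All six species concentrations (μM) at one signal level."""

    M: float
    R: float
    S: float
    MR: float
    SM: float
    SMR: float

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.R, self.S, self.MR, self.SM, self.SMR])

    def conservation_report(self, context: BindingContext, tol: float = 1e-9):
        sums = {
            "R_T": self.R + self.MR + self.SMR,
            "S_T": self.S + self.SM + self.SMR,
            "M_T": self.M + self.SM + self.MR + self.SMR,
        }
        totals = {"R_T": context.R_T, "S_T": context.S_T, "M_T": context.M_T}
        return verify_conservation(sums, totals, tol)


def build_binding_kinetics(
    alpha: float,
    beta: float,
    K1: float,
    forward_rates: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> BindingKinetics:
    """Construct a detailed-balance-consistent rate set from (alpha, beta, K1).

    The dissociation constants follow K3 = beta·K1, K5 = alpha·K1,
    K4 = alpha·beta·K1, so the cycle closes by construction.  The absolute
    rate magnitudes are under-determined by equilibrium data; the forward
    rates ``(k1, k3, k4, k5)`` default to 1 μM⁻¹ s⁻¹ and the dissociation
    rates are k_-i = K_i·k_i.  Steady-state outputs depend on the K_i only.
    """
    if not (alpha > 0 and beta > 0 and K1 > 0):
        raise ParameterError("alpha, beta and K1 must be strictly positive")
    k1, k3, k4, k5 = forward_rates
    if not all(k > 0 for k in forward_rates):
        raise ParameterError("forward rates must be strictly positive")
    K3, K4, K5 = beta * K1, alpha * beta * K1, alpha * K1
    return BindingKinetics(
        k1=k1, k3=k3, k4=k4, k5=k5,
        km1=K1 * k1, km3=K3 * k3, km4=K4 * k4, km5=K5 * k5,
    )


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

# Free-species reconstruction: values in [-_CLIP·scale, 0] (scale = largest
# total) are round-off from solver trial steps and are clipped to 0; anything
# more negative indicates a genuinely inconsistent state and raises.
_CLIP = 1e-9


def _free_species(
    MR: float, SMR: float, SM: float, context: BindingContext, clamp: bool = False
) -> tuple[float, float, float]:
    R = context.R_T - MR - SMR
    S = context.S_T - SM - SMR
    M = context.M_T - SM - MR - SMR
    if clamp:
        # smooth extension: tiny negative excursions from solver trial steps
        # are left in place; the mass-action terms push them back and the
        # vector field stays differentiable at the feasibility boundary
        return M, R, S
    out = []
    scale = max(context.R_T, context.M_T, context.S_T, 1.0)
    for x in (M, R, S):
        if x < -_CLIP * scale:
            raise StateConsistencyError(
                f"complex concentrations exceed totals (free species {x:.3e} μM)"
            )
        out.append(max(x, 0.0))
    return tuple(out)


def binding_rhs(
    complexes, kinetics: BindingKinetics, context: BindingContext,
    clamp: bool = False,
) -> np.ndarray:
    """Time derivatives d([MR], [SMR], [SM])/dt under mass action.

    Free [M], [R], [S] are reconstructed from the conservation relations, so
    the totals are conserved exactly by construction.  With ``clamp=True``
    infeasible inputs are projected onto the feasible region instead of
    raising — stiff-solver trial steps may transiently overshoot the totals,
    and the clamped field simply pushes them back.
    """
    MR, SMR, SM = complexes
    M, R, S = _free_species(MR, SMR, SM, context, clamp=clamp)
    k = kinetics
    dMR = -(k.km1 + k.k4 * S) * MR + k.k1 * R * M + k.km4 * SMR
    dSMR = -(k.km5 + k.km4) * SMR + k.k5 * SM * R + k.k4 * S * MR
    dSM = -(k.km3 + k.k5 * R) * SM + k.k3 * S * M + k.km5 * SMR
    return np.array([dMR, dSMR, dSM])


# ---------------------------------------------------------------------------
# Equilibrium solver (the algebraic route)
# ---------------------------------------------------------------------------

def _two_species_bound(R_T: float, M_T: float, K: float) -> float:
    """Complex concentration for a single reversible binding pair.

    Root of MR² − (R_T + M_T + K)·MR + R_T·M_T = 0 in [0, min(R_T, M_T)].
    """
    b = R_T + M_T + K
    disc = b * b - 4.0 * R_T * M_T
    return 0.5 * (b - np.sqrt(max(disc, 0.0)))


def binding_equilibrium(
    kinetics: BindingKinetics,
    context: BindingContext,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> BindingState:
    """Thermodynamic-equilibrium state of the binding network.

    Solves the three conservation equations in the free concentrations
    (M, R, S), with the complexes eliminated through the equilibrium
    relations MR = M·R/K1, SM = S·M/K3 and SMR = S·M·R/(K3·K5)
    (= S·M·R/(K1·K4) by detailed balance).  A damped fixed-point iteration
    supplies the starting point; a Newton solve polishes the root.  The
    returned state is checked against the totals at 1e-9 relative.
    """
    K1, K3, K4 = kinetics.K1, kinetics.K3, kinetics.K4
    Kt = K1 * K4  # == K3 * K5 by detailed balance
    R_T, M_T, S_T = context.R_T, context.M_T, context.S_T

    if M_T == 0.0:
        state = BindingState(M=0.0, R=R_T, S=S_T, MR=0.0, SM=0.0, SMR=0.0)
        return state
    if S_T == 0.0:
        MR = _two_species_bound(R_T, M_T, K1)
        state = BindingState(
            M=M_T - MR, R=R_T - MR, S=0.0, MR=MR, SM=0.0, SMR=0.0
        )
        return state

    def complexes(M, R, S):
        return M * R / K1, S * M / K3, S * M * R / Kt

    # damped fixed-point iteration on the free species
    M, R, S = M_T, R_T, S_T
    for _ in range(200):
        Mn = M_T / (1.0 + S / K3 + R / K1 + S * R / Kt)
        Rn = R_T / (1.0 + M / K1 + S * M / Kt)
        Sn = S_T / (1.0 + M / K3 + M * R / Kt)
        M, R, S = 0.5 * (M + Mn), 0.5 * (R + Rn), 0.5 * (S + Sn)

    def residual(logx):
        M, R, S = np.exp(logx)
        MR, SM, SMR = complexes(M, R, S)
        return np.array(
            [
                (R + MR + SMR) / R_T - 1.0,
                (S + SM + SMR) / S_T - 1.0,
                (M + SM + MR + SMR) / M_T - 1.0,
            ]
        )

    guess = np.log(np.maximum([M, R, S], 1e-300))
    sol = root(residual, guess, method="hybr", tol=1e-13)
    if not sol.success and np.max(np.abs(residual(sol.x))) > 1e-9:
        raise SteadyStateError(
            f"equilibrium root-finding failed: {sol.message}",
            float(np.max(np.abs(residual(sol.x)))),
        )
    M, R, S = np.exp(sol.x)
    MR, SM, SMR = complexes(M, R, S)
    state = BindingState(M=M, R=R, S=S, MR=MR, SM=SM, SMR=SMR)
    report = state.conservation_report(context)
    if not report.ok:
        raise SteadyStateError(
            f"equilibrium violates conservation: {report.residuals}"
        )
    return state


# ---------------------------------------------------------------------------
# Closed forms (validated numerically against the equilibrium solver)
# ---------------------------------------------------------------------------

def basal_free_regulator(mu, K_R1):
    """Free-regulator fraction [R]/R_T at zero signal.

    Two-species titration in dimensionless form:
    ½·(1 − μ − K_R1 + sqrt((μ+1+K_R1)² − 4μ)).  Accepts arrays.
    """
    mu = np.asarray(mu, dtype=float)
    K_R1 = np.asarray(K_R1, dtype=float)
    if np.any(mu < 0) or np.any(K_R1 <= 0):
        raise ParameterError("require mu >= 0 and K_R1 > 0")
    return 0.5 * (1.0 - mu - K_R1 + np.sqrt((mu + 1.0 + K_R1) ** 2 - 4.0 * mu))


def amplitude_binding(alpha, K_R1, mu):
    """Relative response amplitude A of a binding modulator.

    A = ½·(K_R1(1−α) − sqrt((μ+1+K_R1)² − 4μ) + sqrt((μ+1+αK_R1)² − 4μ)).
    The saturated plateau is the same titration with K_R1 → α·K_R1, so
    sign(A) = sign(α − 1): the cooperativity alone fixes whether the signal
    is an inverse agonist (A > 0) or an agonist (A < 0).  Accepts arrays.
    """
    alpha = np.asarray(alpha, dtype=float)
    K_R1 = np.asarray(K_R1, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(alpha <= 0) or np.any(K_R1 <= 0) or np.any(mu < 0):
        raise ParameterError("require alpha > 0, K_R1 > 0 and mu >= 0")
    return 0.5 * (
        K_R1 * (1.0 - alpha)
        - np.sqrt((mu + 1.0 + K_R1) ** 2 - 4.0 * mu)
        + np.sqrt((mu + 1.0 + alpha * K_R1) ** 2 - 4.0 * mu)
    )


def optimal_modulator_concentration(R_T: float, K1: float, K5: float) -> float:
    """Amplitude-maximizing total modulator concentration (μM).

    M_opt = R_T + sqrt(K1·K5); the modulator must always be in excess over
    the regulator, and more so the weaker the interactions.
    """
    if not (R_T > 0 and K1 > 0 and K5 > 0):
        raise ParameterError("R_T, K1 and K5 must be strictly positive")
    return R_T + np.sqrt(K1 * K5)


def optimal_mu(alpha, K_R1):
    """Dimensionless optimum μ_opt = M_opt/R_T = 1 + K_R1·sqrt(α)."""
    alpha = np.asarray(alpha, dtype=float)
    K_R1 = np.asarray(K_R1, dtype=float)
    if np.any(alpha <= 0) or np.any(K_R1 <= 0):
        raise ParameterError("alpha and K_R1 must be strictly positive")
    return 1.0 + K_R1 * np.sqrt(alpha)


def amplitude_at_optimum(alpha, K_R1):
    """Response amplitude at the optimal modulator concentration.

    A_opt = ½·(K_R1(1−α) − (1−sqrt(α))·sqrt(K_R1·(K_R1(1+sqrt(α))² + 4))).
    Equals amplitude_binding(alpha, K_R1, optimal_mu(alpha, K_R1)).
    """
    alpha = np.asarray(alpha, dtype=float)
    K_R1 = np.asarray(K_R1, dtype=float)
    if np.any(alpha <= 0) or np.any(K_R1 <= 0):
        raise ParameterError("alpha and K_R1 must be strictly positive")
    ra = np.sqrt(alpha)
    return 0.5 * (
        K_R1 * (1.0 - alpha)
        - (1.0 - ra) * np.sqrt(K_R1 * (K_R1 * (1.0 + ra) ** 2 + 4.0))
    )
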