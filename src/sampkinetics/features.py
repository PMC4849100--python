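"""Dose-response feature extraction.

Characterizes a monotone steady-state dose-response curve by the paper-level
descriptors used throughout this package: relative amplitude A (signal-induced
change in free/active regulator over total regulator), qualitative
classification (agonist / inverse agonist / null), EC50 (total signal giving a
half-maximal normalized response), the logarithmic elasticity at the EC50 and
the Hill coefficient h = 2ε (h ≤ 1 graded, h > 1 ultrasensitive), and the
fractional receptor occupancy (signal-bound modulator fraction).

The extraction routines operate on a :class:`ResponseFunction` — any callable
mapping total signal to output concentration, together with its basal and
plateau levels — so they can be exercised on analytic reference curves
(hyperbolas, Hill functions) independently of the kinetic models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.optimize import minimize_scalar

from . import binding as bnd
from . import enzymatic as enz
from .numerics import DEFAULT_SETTINGS, SolverSettings, saturating_signal

NULL_TOL = 1e-9  # |A| below this: no response, EC50/Hill undefined

ModelName = Literal["binding", "enzymatic"]


class NullResponseError(ValueError):
    """EC50/Hill requested for a curve with no discernible response."""


class MonotonicityError(RuntimeError):
    """A computed dose-response curve is not monotone beyond tolerance."""


# ---------------------------------------------------------------------------
# Response-function abstraction
# ---------------------------------------------------------------------------

@dataclass
class ResponseFunction:
    """Steady output as a function of total signal, with its end levels.

    ``output(S_T)`` must be monotone between ``basal`` (S_T = 0) and
    ``plateau`` (S_T → ∞).  ``occupancy(S_T)``, if provided, returns the
    signal-bound modulator fraction at the same steady state.
    """

    output: Callable[[float], float]
    basal: float
    plateau: float
    R_T: float
    s_max: float
    occupancy: Callable[[float], float] | None = None

    def normalized(self, S_T: float) -> float:
        """Normalized response R_n(S_T) ∈ [0, 1], increasing by construction."""
        span = self.plateau - self.basal
        if abs(span) <= NULL_TOL:
            raise NullResponseError("normalization undefined for a flat curve")
        return (self.output(S_T) - self.basal) / span


def make_response_function(
    model: ModelName,
    kinetics,
    context,
    settings: SolverSettings = DEFAULT_SETTINGS,
    method: str = "integrate",
) -> ResponseFunction:
    """Wrap a kinetic model as a ResponseFunction at fixed context.

    ``context.S_T`` is ignored; the signal is the independent variable.
    The binding model output is free [R]; the enzymatic model output is
    active [R'].
    """
    if model == "binding":
        def solve(S_T):
            ctx = bnd.BindingContext(R_T=context.R_T, M_T=context.M_T, S_T=S_T)
            return bnd.binding_equilibrium(kinetics, ctx, settings)

        s_max = saturating_signal(
            [kinetics.K3, kinetics.K4], context.M_T, context.R_T, settings
        )
        out = lambda S_T: solve(S_T).R
        occ = (
            (lambda S_T: (lambda st: (st.SM + st.SMR) / context.M_T)(solve(S_T)))
            if context.M_T > 0
            else None
        )
    elif model == "enzymatic":
        def solve(S_T):
            ctx = enz.EnzymaticContext(R_T=context.R_T, M_T=context.M_T, S_T=S_T)
            return enz.enzymatic_steady_state(kinetics, ctx, settings, method=method)

        s_max = saturating_signal(
            [kinetics.K3, kinetics.K4], context.M_T, context.R_T, settings
        )
        out = lambda S_T: solve(S_T).Rp
        occ = (
            (lambda S_T: (lambda st: (st.SM + st.SMRp) / context.M_T)(solve(S_T)))
            if context.M_T > 0
            else None
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    return ResponseFunction(
        output=out,
        basal=out(0.0),
        plateau=out(s_max),
        R_T=context.R_T,
        s_max=s_max,
        occupancy=occ,
    )


# ---------------------------------------------------------------------------
# Curves and summaries
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseCurve:
    """A sampled dose-response curve plus its end levels (all μM)."""

    S_T: np.ndarray
    output: np.ndarray
    basal: float
    plateau: float
    R_T: float

    @property
    def normalized(self) -> np.ndarray:
        span = self.plateau - self.basal
        if abs(span) <= NULL_TOL:
            raise NullResponseError("normalization undefined for a flat curve")
        return (self.output - self.basal) / span

    @property
    def amplitude(self) -> float:
        return amplitude_numeric(self.basal, self.plateau, self.R_T)


@dataclass
class ResponseSummary:
    """Scalar descriptors of one dose-response curve."""

    amplitude: float
    classification: str
    ec50: float | None = None
    elasticity: float | None = None
    hill: float | None = None
    occupancy_at_ec50: float | None = None

    def as_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "classification": self.classification,
            "EC50_uM": self.ec50,
            "elasticity": self.elasticity,
            "hill": self.hill,
            "occupancy_at_EC50": self.occupancy_at_ec50,
        }


@dataclass
class OptimalContext:
    """Amplitude-optimal signaling context for a given modulator."""

    M_T: float
    amplitude: float
    kappa: float | None = None
    at_bound: bool = False


def dose_response(
    model: ModelName,
    kinetics,
    context,
    n_points: int = 41,
    decades: float = 6.0,
    settings: SolverSettings = DEFAULT_SETTINGS,
    method: str = "integrate",
    monotone_tol: float = 1e-7,
) -> DoseResponseCurve:
    """Steady-state dose-response curve on a log-spaced signal grid.

    The grid spans ``decades`` below the saturating signal level.  Curves of
    these models are monotone in S_T; a violation beyond ``monotone_tol``
    (relative to the curve span) raises :class:`MonotonicityError`, which
    signals a solver or parameter problem rather than real behavior.
    """
    rf = make_response_function(model, kinetics, context, settings, method)
    grid = np.logspace(np.log10(rf.s_max) - decades, np.log10(rf.s_max), n_points)
    out = np.array([rf.output(s) for s in grid])
    span = rf.plateau - rf.basal
    if abs(span) > NULL_TOL:
        steps = np.diff(np.concatenate([[rf.basal], out])) * np.sign(span)
        if np.any(steps < -monotone_tol * abs(span)):
            raise MonotonicityError("dose-response curve is not monotone")
    return DoseResponseCurve(
        S_T=grid, output=out, basal=rf.basal, plateau=rf.plateau, R_T=context.R_T
    )


def amplitude_numeric(basal: float, plateau: float, R_T: float) -> float:
    """Relative amplitude A = (plateau − basal)/R_T."""
    if not R_T > 0:
        raise bnd.ParameterError("R_T must be strictly positive")
    return (plateau - basal) / R_T


def classify_response(A: float, tol: float = NULL_TOL) -> str:
    """'inverse-agonist' (A > tol), 'agonist' (A < −tol) or 'null'."""
    if A > tol:
        return "inverse-agonist"
    if A < -tol:
        return "agonist"
    return "null"


def ec50_from_function(rf: ResponseFunction, tol: float = 1e-6) -> float:
    """EC50 by bisection in log S_T on the normalized (monotone) curve."""
    if abs(rf.plateau - rf.basal) / rf.R_T <= NULL_TOL:
        raise NullResponseError("EC50 undefined: response amplitude below tolerance")
    hi = np.log10(rf.s_max)
    lo = hi - 14.0
    # R_n is increasing; find the half-maximal crossing
    if rf.normalized(10.0**lo) >= 0.5:
        raise NullResponseError("EC50 below the resolvable signal range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rn = rf.normalized(10.0**mid)
        if abs(rn - 0.5) < tol:
            return 10.0**mid
        if rn < 0.5:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


def hill_from_function(
    rf: ResponseFunction, ec50: float, log_step: float = 0.01
) -> tuple[float, float]:
    """Elasticity ε and Hill coefficient h = 2ε at the EC50.

    ε is the central finite difference of log R_n against log S_T over
    ``log_step`` decades.  Normalization already makes R_n increasing for
    agonist curves, so h ≥ 0 by construction.
    """
    up = rf.normalized(ec50 * 10.0**log_step)
    dn = rf.normalized(ec50 / 10.0**log_step)
    if up <= 0 or dn <= 0:
        raise NullResponseError("elasticity ill-conditioned at the EC50")
    eps = (np.log10(up) - np.log10(dn)) / (2.0 * log_step)
    return float(eps), float(2.0 * eps)


def receptor_occupancy(state, M_T: float) -> float:
    """Fraction of modulator bound to signal: ([SM] + [SMR*])/M_T."""
    if not M_T > 0:
        raise bnd.ParameterError("occupancy undefined for M_T = 0")
    ternary = state.SMR if hasattr(state, "SMR") else state.SMRp
    return (state.SM + ternary) / M_T


def summarize_response(
    model: ModelName,
    kinetics,
    context,
    settings: SolverSettings = DEFAULT_SETTINGS,
    method: str = "integrate",
) -> ResponseSummary:
    """Full feature set (A, class, EC50, ε, h, occupancy) for one context."""
    rf = make_response_function(model, kinetics, context, settings, method)
    A = amplitude_numeric(rf.basal, rf.plateau, context.R_T)
    cls = classify_response(A)
    if cls == "null":
        return ResponseSummary(amplitude=A, classification=cls)
    ec = ec50_from_function(rf)
    eps, h = hill_from_function(rf, ec)
    occ = rf.occupancy(ec) if rf.occupancy is not None else None
    return ResponseSummary(
        amplitude=A, classification=cls, ec50=ec, elasticity=eps, hill=h,
        occupancy_at_ec50=occ,
    )


# ---------------------------------------------------------------------------
# Context optimization
# ---------------------------------------------------------------------------

def optimize_context(
    model: ModelName,
    kinetics,
    R_T: float,
    mu_bounds: tuple[float, float] = (1e-3, 1e4),
    kappa_bounds: tuple[float, float] | None = None,
) -> OptimalContext:
    """Signaling context maximizing the output dynamic range |A|.

    Binding model: analytic, M_opt = R_T + sqrt(K1·K5).  Enzymatic model:
    bounded log-scale search on the closed-form amplitude over μ (and κ if
    ``kappa_bounds`` is given, a 2-D nested search).  The amplitude
    magnitude is optimized because for agonists A < 0 and the dynamic range
    is |A|.  A result at a bound is flagged, not silently accepted.
    """
    if model == "binding":
        M_opt = bnd.optimal_modulator_concentration(R_T, kinetics.K1, kinetics.K5)
        A = float(
            bnd.amplitude_binding(kinetics.alpha, kinetics.K1 / R_T, M_opt / R_T)
        )
        return OptimalContext(M_T=M_opt, amplitude=A)

    if model != "enzymatic":
        raise ValueError(f"unknown model {model!r}")

    aB, aE, K_r = kinetics.alpha_B, kinetics.alpha_E, kinetics.K_M / R_T
    k2 = kinetics.k2

    def neg_abs_A(log_mu, kappa, gamma):
        mu = 10.0**log_mu
        iota = k2 / (gamma + kappa)
        kr = kappa / (gamma + kappa)
        return -abs(float(enz.amplitude_enzymatic(aB, aE, K_r, mu, iota, kr)))

    def best_mu(kappa):
        res = minimize_scalar(
            neg_abs_A,
            bounds=(np.log10(mu_bounds[0]), np.log10(mu_bounds[1])),
            args=(kappa, kinetics.gamma),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return res.x, -res.fun

    if kappa_bounds is None:
        log_mu, bestA = best_mu(kinetics.kappa)
        kappa_opt = None
    else:
        def neg_over_kappa(log_kappa):
            _, a = best_mu(10.0**log_kappa)
            return -a

        res = minimize_scalar(
            neg_over_kappa,
            bounds=(np.log10(kappa_bounds[0]), np.log10(kappa_bounds[1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        kappa_opt = 10.0**res.x
        log_mu, bestA = best_mu(kappa_opt)

    mu_opt = 10.0**log_mu
    at_bound = bool(
        np.isclose(mu_opt, mu_bounds[0], rtol=1e-3)
        or np.isclose(mu_opt, mu_bounds[1], rtol=1e-3)
        or (
            kappa_bounds is not None
            and (
                np.isclose(kappa_opt, kappa_bounds[0], rtol=1e-3)
                or np.isclose(kappa_opt, kappa_bounds[1], rtol=1e-3)
            )
        )
    )
    return OptimalContext(
        M_T=mu_opt * R_T, amplitude=bestA, kappa=kappa_opt, at_bound=at_bound
    )
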