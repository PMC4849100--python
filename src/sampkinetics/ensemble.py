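"""Context-robustness and design-space analyses.

A modulator's qualitative response (activation vs. repression of the
regulator) may or may not survive changes in the signaling context (the
Class II parameters: relative concentrations, kinase activity).  This module
quantifies that robustness by Latin-hypercube sampling of contexts and the
binary "response entropy" H(p) of the activation frequency p, and provides
the parameter-space scans used to map modulator design space: amplitude maps
over the cooperativities, titration scans over modulator concentration, and
context landscapes over (μ, κ/γ).

Ensembles and landscapes evaluate the closed-form amplitudes (validated
elsewhere against the mass-action steady states) so that 10⁴-sample scans
run in milliseconds; ``ode_check`` switches a subset to full steady-state
evaluation for spot validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import binding as bnd
from . import enzymatic as enz
from . import features as feat
from .binding import ParameterError
from .numerics import DEFAULT_SETTINGS, SolverSettings

#: Class II ranges of the robustness analysis: K_r, iota, mu in [0.1, 10],
#: kappa_r in [0.01, 1].
DEFAULT_CLASS_II_RANGES = {
    "K_r": (0.1, 10.0),
    "iota": (0.1, 10.0),
    "mu": (0.1, 10.0),
    "kappa_r": (0.01, 1.0),
}

AMPLITUDE_TOL = 1e-9  # |A| at or below this: unclassified, excluded from p


@dataclass(frozen=True)
class SamplingSpec:
    """Latin-hypercube sampling plan over Class II parameters.

    ``scale`` applies to every marginal: "log" stratifies uniformly in
    log10 (the ranges span decades), "linear" in the raw value.
    """

    ranges: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_II_RANGES))
    n: int = 10_000
    seed: int | None = None
    scale: str = "log"

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("need at least 2 samples")
        if self.scale not in ("log", "linear"):
            raise ParameterError("scale must be 'log' or 'linear'")
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ParameterError(f"range for {name} must be positive and ordered")


def latin_hypercube(spec: SamplingSpec) -> pd.DataFrame:
    """Stratified sample table: one point per stratum per dimension.

    Reproducible under a fixed seed; columns follow ``spec.ranges`` order.
    """
    names = list(spec.ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    u = sampler.random(spec.n)
    cols = {}
    for j, name in enumerate(names):
        lo, hi = spec.ranges[name]
        if spec.scale == "log":
            cols[name] = 10.0 ** (np.log10(lo) + u[:, j] * (np.log10(hi) - np.log10(lo)))
        else:
            cols[name] = lo + u[:, j] * (hi - lo)
    return pd.DataFrame(cols)


def response_entropy(p) -> float:
    """Binary entropy H(p) = −p·log2(p) − (1−p)·log2(1−p), in bits.

    H = 0 iff p ∈ {0, 1} (context-robust qualitative response); H = 1 at
    p = ½.  Uses the limit convention 0·log 0 = 0.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must lie in [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


@dataclass
class EnsembleResult:
    """Robustness statistics of one modulator over a context ensemble."""

    samples: pd.DataFrame
    amplitudes: np.ndarray
    p: float
    entropy: float
    mean_amplitude: float
    n_null: int


class DegenerateEnsembleError(RuntimeError):
    """Every sampled context produced a null response."""


def ensemble_response(
    alpha_E: float,
    alpha_B: float,
    spec: SamplingSpec | None = None,
    ode_check: int = 0,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> EnsembleResult:
    """Closed-form amplitude over a Class II ensemble, with p, H and ⟨A⟩.

    ``p`` is the activation frequency: the fraction of classified samples
    (|A| > 1e-9) with A > 0.  ``ode_check`` > 0 additionally re-evaluates
    that many samples through the mass-action steady state (unit rates,
    R_T = 1 μM, rates reconstructed from the sampled Class II values) and
    asserts agreement — a guard against drift between the closed form and
    the kinetic model.
    """
    spec = spec or SamplingSpec()
    table = latin_hypercube(spec)
    A = np.asarray(
        enz.amplitude_enzymatic(
            alpha_B, alpha_E, table["K_r"], table["mu"], table["iota"], table["kappa_r"]
        )
    )
    classified = np.abs(A) > AMPLITUDE_TOL
    n_null = int((~classified).sum())
    if not classified.any():
        raise DegenerateEnsembleError(
            "all sampled contexts give |A| below tolerance; "
            "the modulator has no cooperativity to act through"
        )
    p = float((A[classified] > 0).mean())
    if ode_check > 0:
        idx = np.linspace(0, len(table) - 1, min(ode_check, len(table))).astype(int)
        for i in idx:
            row = table.iloc[i]
            a_ode = _ode_amplitude_from_class_ii(
                alpha_E, alpha_B, row["K_r"], row["mu"], row["iota"], row["kappa_r"],
                settings,
            )
            # the numeric plateau is saturation-limited, so allow a small
            # absolute floor alongside the relative criterion
            if abs(a_ode - A[i]) > max(1e-5, 1e-4 * abs(A[i])):
                raise RuntimeError(
                    f"closed-form/ODE mismatch at sample {i}: {A[i]} vs {a_ode}"
                )
    return EnsembleResult(
        samples=table,
        amplitudes=A,
        p=p,
        entropy=response_entropy(p),
        mean_amplitude=float(A.mean()),
        n_null=n_null,
    )


def _ode_amplitude_from_class_ii(
    alpha_E, alpha_B, K_r, mu, iota, kappa_r, settings
) -> float:
    """Amplitude via steady states for one dimensionless Class II point.

    Reconstructs a concrete rate set realizing (K_r, μ, ι, κ_r) at
    R_T = 1 μM with κ + γ = 1 s⁻¹ and unit reference rates.
    """
    R_T = 1.0
    kappa = kappa_r
    gamma = 1.0 - kappa_r
    k2 = iota  # since gamma + kappa = 1
    kin = enz.build_enzymatic_kinetics(
        alpha_E=alpha_E, alpha_B=alpha_B, beta_E=1.0, K_M=K_r * R_T,
        kappa=kappa, gamma=gamma, k2=k2,
    )
    rf = feat.make_response_function(
        "enzymatic",
        kin,
        enz.EnzymaticContext(R_T=R_T, M_T=mu * R_T),
        settings,
        method="integrate",
    )
    return feat.amplitude_numeric(rf.basal, rf.plateau, R_T)


# ---------------------------------------------------------------------------
# Parameter-space scans
# ---------------------------------------------------------------------------

def titration_scan(
    kinetics: bnd.BindingKinetics,
    M_T_grid,
    R_T: float,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Free regulator vs. total modulator at zero and saturating signal.

    Returns a frame with columns ``M_T_uM``, ``R_basal_uM``, ``R_sat_uM``
    and ``amplitude``; the vertical gap between the two titration curves is
    the output dynamic range at that modulator level, and its maximum sits
    at M_opt = R_T + sqrt(K1·K5).
    """
    rows = []
    for M_T in np.asarray(M_T_grid, dtype=float):
        basal = bnd.binding_equilibrium(
            kinetics, bnd.BindingContext(R_T=R_T, M_T=M_T, S_T=0.0), settings
        ).R
        if M_T > 0:
            from .numerics import saturating_signal

            s_sat = saturating_signal([kinetics.K3, kinetics.K4], M_T, R_T, settings)
            sat = bnd.binding_equilibrium(
                kinetics, bnd.BindingContext(R_T=R_T, M_T=M_T, S_T=s_sat), settings
            ).R
        else:
            sat = basal
        rows.append((M_T, basal, sat, (sat - basal) / R_T))
    return pd.DataFrame(
        rows, columns=["M_T_uM", "R_basal_uM", "R_sat_uM", "amplitude"]
    )


def context_landscape(
    alpha_B: float,
    alpha_E: float,
    K_M: float,
    R_T: float,
    k2: float,
    gamma: float,
    mu_grid,
    kinase_ratio_grid,
) -> pd.DataFrame:
    """Amplitude over the (μ, κ/γ) context plane via the closed form.

    For each cell, κ = ratio·γ and the dimensionless ι, κ_r are recomputed.
    Long-format frame with columns ``mu``, ``kappa_over_gamma``,
    ``amplitude``.  Along each κ/γ column of an alpha_E = 1 enzyme, the
    amplitude ridge tracks the closed-form optimum μ_opt.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    ratio_grid = np.asarray(kinase_ratio_grid, dtype=float)
    K_r = K_M / R_T
    rows = []
    for ratio in ratio_grid:
        kappa = ratio * gamma
        iota = k2 / (gamma + kappa)
        kr = kappa / (gamma + kappa)
        A = enz.amplitude_enzymatic(alpha_B, alpha_E, K_r, mu_grid, iota, kr)
        rows.extend(zip(mu_grid, np.full_like(mu_grid, ratio), np.atleast_1d(A)))
    return pd.DataFrame(rows, columns=["mu", "kappa_over_gamma", "amplitude"])


@dataclass
class DesignGrid:
    """Per-cell response features over a rectangular Class I grid."""

    axis_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    features: dict  # name -> 2D array (axis1 × axis2); NaN flags a null cell

    def to_frame(self) -> pd.DataFrame:
        """Long format: axis1, axis2, feature, value."""
        rows = []
        for fname, grid in self.features.items():
            for i, a in enumerate(self.axis1):
                for j, b in enumerate(self.axis2):
                    rows.append((a, b, fname, grid[i, j]))
        return pd.DataFrame(rows, columns=[*self.axis_names, "feature", "value"])


def design_space_map(
    model: feat.ModelName,
    axis1,
    axis2,
    feature_names=("amplitude", "hill", "ec50", "occupancy"),
    K1: float = 1.0,
    R_T: float = 1.0,
    enzymatic_base: enz.EnzymaticKinetics | None = None,
    kappa_bounds: tuple[float, float] | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
    method: str = "integrate",
) -> DesignGrid:
    """Feature maps over modulator design space at the optimal context.

    Binding model: axes are (alpha, beta) at fixed K1 and R_T; each cell's
    modulator concentration is set to the analytic optimum before features
    are extracted.  Enzymatic model: axes are (alpha_E, beta_E) with the
    binding cooperativity of ``enzymatic_base`` (typically alpha_B = 1) and
    its reference rates; [M_T] — and κ, when ``kappa_bounds`` is given — are
    optimized numerically per cell.  Cells with a null response carry NaN
    features; per-cell solver failures are flagged the same way rather than
    aborting the scan.
    """
    axis1 = np.asarray(axis1, dtype=float)
    axis2 = np.asarray(axis2, dtype=float)
    grids = {f: np.full((axis1.size, axis2.size), np.nan) for f in feature_names}

    for i, a in enumerate(axis1):
        for j, b in enumerate(axis2):
            try:
                if model == "binding":
                    kin = bnd.build_binding_kinetics(alpha=a, beta=b, K1=K1)
                    opt = feat.optimize_context("binding", kin, R_T)
                    ctx = bnd.BindingContext(R_T=R_T, M_T=opt.M_T)
                    kappa = None
                else:
                    if enzymatic_base is None:
                        raise ParameterError(
                            "enzymatic design map needs an enzymatic_base rate set"
                        )
                    base = enzymatic_base
                    kin = enz.build_caption_kinetics(
                        alpha_E=a, alpha_B=base.alpha_B, kappa=base.kappa,
                        gamma=base.gamma, beta_E=b, k2=base.k2,
                        km1=base.km1, km4=base.km4, km5=base.km5,
                        k1=base.k1, k3=base.k3,
                    )
                    opt = feat.optimize_context(
                        "enzymatic", kin, R_T, kappa_bounds=kappa_bounds
                    )
                    if opt.kappa is not None:
                        kin = enz.EnzymaticKinetics(
                            **{
                                **{f: getattr(kin, f) for f in (
                                    "k1", "km1", "k2", "k3", "km3", "k4", "km4",
                                    "k5", "km5", "k6", "gamma",
                                )},
                                "kappa": opt.kappa,
                            }
                        )
                    ctx = enz.EnzymaticContext(R_T=R_T, M_T=opt.M_T)
                summary = feat.summarize_response(
                    model, kin, ctx, settings, method=method
                )
            except (feat.NullResponseError, ParameterError):
                continue
            values = {
                "amplitude": summary.amplitude,
                "hill": summary.hill,
                "ec50": summary.ec50,
                "occupancy": summary.occupancy_at_ec50,
            }
            for f in feature_names:
                v = values.get(f)
                grids[f][i, j] = np.nan if v is None else v

    names = ("alpha", "beta") if model == "binding" else ("alpha_E", "beta_E")
    return DesignGrid(axis_names=names, axis1=axis1, axis2=axis2, features=grids)
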