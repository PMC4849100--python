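"""Built-in parameter sets.

Each preset encodes one of the published figure setups (or the RapA-PhrA
estimate) verbatim, with the under-determined rate magnitudes fixed the way
the corresponding caption fixes them.  Every preset's kinetics object passes
the detailed-balance / cycle invariants at load time, because the model
constructors validate on instantiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import binding as bnd
from . import enzymatic as enz
from .ensemble import SamplingSpec

MU_SERIES_FIG4 = (0.1, 0.32, 1.0, 3.2, 10.0)
MT_SERIES_FIG7 = (0.5, 1.5, 3.0, 7.0, 10.0, 20.0)  # μM


@dataclass(frozen=True)
class Preset:
    """A named, fully resolved parameter set.

    ``contexts`` lists the concentration combinations the setup sweeps
    (empty for sampling-only presets); ``params`` carries auxiliary scalars
    (e.g. rates entering a context landscape); ``note`` records provenance.
    """

    name: str
    model: str  # "binding" | "enzymatic" | "sampling"
    kinetics: object | None
    contexts: tuple = ()
    sampling: SamplingSpec | None = None
    params: dict = field(default_factory=dict)
    note: str = ""


def _binding_panel(name, alpha, beta, note):
    kin = bnd.build_binding_kinetics(alpha=alpha, beta=beta, K1=1.0)
    ctxs = tuple(
        bnd.BindingContext(R_T=1.0, M_T=mu * 1.0) for mu in MU_SERIES_FIG4
    )
    return Preset(name=name, model="binding", kinetics=kin, contexts=ctxs, note=note)


def _fig7_panel(name, alpha_E, alpha_B, note):
    kin = enz.build_caption_kinetics(
        alpha_E=alpha_E, alpha_B=alpha_B, kappa=1.0, gamma=1.0
    )
    ctxs = tuple(
        enz.EnzymaticContext(R_T=10.0, M_T=M_T) for M_T in MT_SERIES_FIG7
    )
    return Preset(name=name, model="enzymatic", kinetics=kin, contexts=ctxs, note=note)


def _fig9(name, alpha_E, alpha_B, note):
    # kinase activity κ is the landscape variable; the stored kinetics uses
    # κ = γ as a neutral placeholder, the scan rebuilds ι and κ_r per cell
    params = dict(
        alpha_E=alpha_E, alpha_B=alpha_B, K_M=1.2, R_T=2.0, k2=0.72, gamma=1.2e-4
    )
    kin = enz.build_enzymatic_kinetics(
        alpha_E=alpha_E, alpha_B=alpha_B, beta_E=1.0, K_M=params["K_M"],
        kappa=params["gamma"], gamma=params["gamma"], k2=params["k2"],
    )
    return Preset(name=name, model="enzymatic", kinetics=kin, params=params, note=note)


def _make_presets() -> dict[str, Preset]:
    presets: dict[str, Preset] = {}

    fig4 = {
        "fig4a": (10.0, 0.1), "fig4b": (0.1, 0.1),
        "fig4c": (10.0, 1.0), "fig4d": (0.1, 1.0),
        "fig4e": (10.0, 10.0), "fig4f": (0.1, 10.0),
    }
    for name, (alpha, beta) in fig4.items():
        presets[name] = _binding_panel(
            name, alpha, beta,
            f"dose-response panel: alpha={alpha}, beta={beta}, "
            f"K1 = R_T = 1 uM, mu in {MU_SERIES_FIG4}",
        )

    for tag, alpha in (("fig5_pos", 0.1), ("fig5_neg", 10.0)):
        presets[tag] = Preset(
            name=tag,
            model="binding",
            kinetics=bnd.build_binding_kinetics(alpha=alpha, beta=1.0, K1=5.0),
            contexts=(bnd.BindingContext(R_T=1.0, M_T=1.0),),
            params=dict(R_T=1.0),
            note=f"titration setup: R_T = 1 uM, K1 = 5 uM, alpha = {alpha}",
        )

    fig7 = {
        "fig7a": (10.0, 0.1), "fig7b": (10.0, 10.0),
        "fig7c": (0.1, 10.0), "fig7d": (0.1, 0.1),
    }
    for name, (aE, aB) in fig7.items():
        presets[name] = _fig7_panel(
            name, aE, aB,
            f"enzymatic dose-response panel: alpha_E={aE}, alpha_B={aB}, "
            "R_T = 10 uM, kappa = gamma = k-1 = k2 = k-3 = k-4 = k-5 = 1/s, "
            "k1 = k3 = 1/(uM s); k4, k5, k6 from the allosteric parameters "
            "and the cycle constraint",
        )

    presets["fig8"] = Preset(
        name="fig8",
        model="sampling",
        kinetics=None,
        sampling=SamplingSpec(),
        note="robustness ensemble: K_r, iota, mu in [0.1, 10], "
             "kappa_r in [0.01, 1], n = 10^4 Latin-hypercube samples",
    )

    presets["fig9a"] = _fig9("fig9a", 0.37, 5.0, "coherent enzyme landscape")
    presets["fig9b"] = _fig9("fig9b", 1.0, 5.0, "binding-allostery-only landscape")
    presets["fig9c"] = _fig9("fig9c", 0.37, 1.0, "enzymatic-allostery-only landscape")

    rapa_kin = enz.build_caption_kinetics(
        alpha_E=0.37, alpha_B=1.0, beta_E=3.6, kappa=1.0, gamma=0.1
    )
    presets["fig10"] = Preset(
        name="fig10",
        model="enzymatic",
        kinetics=rapa_kin,
        contexts=(enz.EnzymaticContext(R_T=10.0, M_T=10.0),),
        params=dict(R_T=10.0),
        note="design-space base: alpha_B = 1, R_T = 10 uM, "
             "kappa = k-1 = k2 = k-3 = k-4 = k-5 = 1/s, gamma = 0.1/s, "
             "k1 = k3 = 1/(uM s); k-3, k4, k5, k6 from the allosteric "
             "parameters and the cycle constraint",
    )
    presets["rapA"] = Preset(
        name="rapA",
        model="enzymatic",
        kinetics=rapa_kin,
        contexts=(enz.EnzymaticContext(R_T=10.0, M_T=10.0),),
        params=dict(R_T=10.0),
        note="RapA-PhrA estimate: alpha_B = 1, alpha_E = 0.37, beta_E = 3.6; "
             "rates as in the design-space base",
    )
    return presets


PRESETS: dict[str, Preset] = _make_presets()


def load_preset(name: str) -> Preset:
    """Return a named preset; unknown names list what is available."""
    try:
        return PRESETS[name]
    except KeyError:
        available = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; available: {available}") from None
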