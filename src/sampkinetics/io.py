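"""Config parsing and result writers.

Configs are YAML or JSON mappings with the flat key schema below; unknown
keys are rejected so that typos fail loudly.  Output CSVs carry a leading
units comment; JSON summaries embed provenance (package version, seed,
solver settings, config hash) with deterministic field ordering so that
re-running a config reproduces the file byte-for-byte apart from nothing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import binding as bnd
from . import enzymatic as enz
from .binding import ParameterError

BINDING_KEYS = {"alpha", "beta", "K1_uM", "R_T_uM", "M_T_uM"}
ENZYMATIC_KEYS = {
    "alpha_E", "alpha_B", "beta_E", "K_M_uM",
    "kappa_per_s", "gamma_per_s", "k2_per_s", "R_T_uM", "M_T_uM",
}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def parse_model_config(config: dict, model: str):
    """Validate a config block and build (kinetics, context) for ``model``."""
    allowed = BINDING_KEYS if model == "binding" else ENZYMATIC_KEYS
    unknown = set(config) - allowed
    if unknown:
        raise ParameterError(
            f"unknown config keys for {model} model: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    missing = allowed - set(config) - {"M_T_uM", "beta_E"}
    if missing:
        raise ParameterError(f"missing config keys: {sorted(missing)}")
    if model == "binding":
        kin = bnd.build_binding_kinetics(
            alpha=float(config["alpha"]),
            beta=float(config["beta"]),
            K1=float(config["K1_uM"]),
        )
        ctx = bnd.BindingContext(
            R_T=float(config["R_T_uM"]), M_T=float(config.get("M_T_uM", 0.0))
        )
    else:
        kin = enz.build_enzymatic_kinetics(
            alpha_E=float(config["alpha_E"]),
            alpha_B=float(config["alpha_B"]),
            beta_E=float(config.get("beta_E", 1.0)),
            K_M=float(config["K_M_uM"]),
            kappa=float(config["kappa_per_s"]),
            gamma=float(config["gamma_per_s"]),
            k2=float(config["k2_per_s"]),
        )
        ctx = enz.EnzymaticContext(
            R_T=float(config["R_T_uM"]), M_T=float(config.get("M_T_uM", 0.0))
        )
    return kin, ctx


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_curve_csv(curve, path: str | Path, occupancy=None) -> None:
    """Dose-response curve as CSV with a units header comment.

    Columns: S_T_uM, R_free_uM (binding) / output concentration, R_normalized,
    and occupancy when supplied.
    """
    path = Path(path)
    frame = pd.DataFrame({"S_T_uM": curve.S_T, "R_free_uM": curve.output})
    try:
        frame["R_normalized"] = curve.normalized
    except Exception:
        frame["R_normalized"] = float("nan")
    if occupancy is not None:
        frame["occupancy"] = occupancy
    with path.open("w") as fh:
        fh.write("# units: concentrations in uM; occupancy dimensionless\n")
        frame.to_csv(fh, index=False)


def write_frame_csv(frame: pd.DataFrame, path: str | Path, units: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if units:
            fh.write(f"# units: {units}\n")
        frame.to_csv(fh, index=False)


def write_summary_json(
    payload: dict,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    settings=None,
) -> None:
    """JSON summary with provenance, deterministically ordered."""
    doc = {
        "package": "sampkinetics",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "solver_settings": (
            {k: getattr(settings, k) for k in settings.__dataclass_fields__}
            if settings is not None
            else None
        ),
        "results": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
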