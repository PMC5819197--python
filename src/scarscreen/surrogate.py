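"""Reference surrogate wound-healing model.

A compact 12-state injury-initiated kinetic model covering the inflammatory
and proliferative phases of cutaneous wound healing.  An injury signal of
platelet degranulation (P) recruits inflammatory cells (I), which hand off to
repair macrophages (M).  TGF-beta (T) — produced by platelets, macrophages and
fibroblasts — drives fibroblast (F) recruitment; fibroblasts additionally
self-renew logistically and undergo apoptosis.  Fibroblasts deposit
fibronectin (FN) and collagen (COL) under TGF-beta stimulation; collagen is
remodelled by MMP-9 (M9), which TIMP-1 (T1) inhibits.  IL-6 (C6) and CXCL8
(C8) are inflammatory cytokines; IL-10 (I10), produced by repair macrophages,
dampens inflammation and enhances TIMP-1 production, coupling the
anti-inflammatory axis to matrix remodelling.

States
------
P platelets · I inflammatory cells · M repair macrophages · F fibroblasts ·
T TGF-beta · C6 IL-6 · C8 CXCL8 · I10 IL-10 · M9 MMP-9 · T1 TIMP-1 ·
FN fibronectin · COL collagen

All concentrations are in arbitrary units (the downstream analysis uses only
fold changes and within-cohort distributions); rates are per day.

Equations
---------
dP/dt   = -kP*P
dI/dt   = rI*P + rI8*C8/(K8+C8) / (1+I10/KI10) - dI*I
dM/dt   = rM*I - dM*M
dF/dt   = rF*T/(KT+T) + gF*F*(1-F/Fmax) - aF*F
dT/dt   = pTP*P + pTM*M + pTF*F - dT*T
dC6/dt  = p6*I / (1+I10/KI10) - d6*C6
dC8/dt  = p8P*P + p8I*I - d8*C8
dI10/dt = p10*M - d10*I10
dM9/dt  = p9*I - d9*M9
dT1/dt  = pT1M*M + pT1F*F*(1 + e10*I10/(K10e+I10)) - dT1*T1
dFN/dt  = pFN*F*T/(KT+T) - dFN*FN
dCOL/dt = pC*F*T/(KT+T) - dC*COL*M9/(1 + T1/KT1)

Every loss term is proportional to its own state, so the non-negative orthant
is forward-invariant for positive parameters.  The shipped default parameter
vector was produced by the seeded calibration search in
:mod:`scarscreen.calibration` and is packaged in ``data/reference_model.yaml``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .model import KineticModelSpec

__all__ = ["STATE_NAMES", "PARAM_NAMES", "surrogate_rhs", "build_surrogate",
           "load_reference_model", "model_from_config", "model_to_config"]

STATE_NAMES = (
    "P", "I", "M", "F", "T", "C6", "C8", "I10", "M9", "T1", "FN", "COL",
)

PARAM_NAMES = (
    "kP",
    "rI", "rI8", "K8", "KI10", "dI",
    "rM", "dM",
    "rF", "KT", "gF", "Fmax", "aF",
    "pTP", "pTM", "pTF", "dT",
    "p6", "d6",
    "p8P", "p8I", "d8",
    "p10", "d10",
    "p9", "d9",
    "pT1M", "pT1F", "e10", "K10e", "dT1",
    "pFN", "dFN",
    "pC", "dC", "KT1",
)

MARKER_ROLES = {
    "collagen": "COL",
    "fibroblast": "F",
    "screened": ("T", "C6", "C8", "I10", "M9", "T1", "FN"),
}

#: injury state: a unit bolus of platelet signal, everything else at zero
INITIAL_STATE = np.array([1.0] + [0.0] * 11)


def surrogate_rhs(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
    P, I, M, F, T, C6, C8, I10, M9, T1, FN, COL = y
    (kP,
     rI, rI8, K8, KI10, dI,
     rM, dM,
     rF, KT, gF, Fmax, aF,
     pTP, pTM, pTF, dT,
     p6, d6,
     p8P, p8I, d8,
     p10, d10,
     p9, d9,
     pT1M, pT1F, e10, K10e, dT1,
     pFN, dFN,
     pC, dC, KT1) = p
    inh10 = 1.0 / (1.0 + I10 / KI10)   # IL-10 suppression of inflammation
    sT = T / (KT + T)                  # saturating TGF-beta stimulus
    return np.array([
        -kP * P,
        rI * P + rI8 * C8 / (K8 + C8) * inh10 - dI * I,
        rM * I - dM * M,
        rF * sT + gF * F * (1.0 - F / Fmax) - aF * F,
        pTP * P + pTM * M + pTF * F - dT * T,
        p6 * I * inh10 - d6 * C6,
        p8P * P + p8I * I - d8 * C8,
        p10 * M - d10 * I10,
        p9 * I - d9 * M9,
        pT1M * M + pT1F * F * (1.0 + e10 * I10 / (K10e + I10)) - dT1 * T1,
        pFN * F * sT - dFN * FN,
        pC * F * sT - dC * COL * M9 / (1.0 + T1 / KT1),
    ])


def build_surrogate(params, name: str = "reference-surrogate") -> KineticModelSpec:
    """Assemble a :class:`KineticModelSpec` for the surrogate equations."""
    return KineticModelSpec(
        state_names=STATE_NAMES,
        param_names=PARAM_NAMES,
        default_params=np.asarray(params, dtype=float),
        initial_state=INITIAL_STATE,
        rhs=surrogate_rhs,
        marker_roles=MARKER_ROLES,
        name=name,
    )


def model_from_config(config: dict) -> KineticModelSpec:
    """Build the surrogate from a structured config dictionary.

    The config carries names, defaults, initial state and role map so a user
    can rescale or re-calibrate the surrogate without touching code.  Only
    the surrogate equations are supported; a different RHS must be supplied
    programmatically as its own :class:`KineticModelSpec`.
    """
    params = config["parameters"]
    values = np.array([params[name] for name in PARAM_NAMES], dtype=float)
    missing = set(params) - set(PARAM_NAMES)
    if missing:
        raise ValueError(f"unknown surrogate parameters: {sorted(missing)}")
    model = build_surrogate(values, name=config.get("name", "reference-surrogate"))
    if "initial_state" in config:
        init = np.array(
            [config["initial_state"][s] for s in STATE_NAMES], dtype=float
        )
        from dataclasses import replace

        model = replace(model, initial_state=init)
    return model


def model_to_config(model: KineticModelSpec) -> dict:
    return {
        "name": model.name,
        "parameters": {
            n: float(v) for n, v in zip(model.param_names, model.default_params)
        },
        "initial_state": {
            n: float(v) for n, v in zip(model.state_names, model.initial_state)
        },
        "marker_roles": {
            "collagen": model.collagen_state,
            "fibroblast": model.fibroblast_state,
            "screened": list(model.screened_states),
        },
    }


def load_reference_model() -> KineticModelSpec:
    """Load the packaged, calibrated reference surrogate."""
    text = (
        resources.files("scarscreen.data")
        .joinpath("reference_model.yaml")
        .read_text()
    )
    return model_from_config(yaml.safe_load(text))
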