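"""The two built-in pathway models, with the published rate constants.

G2-M transition (fission yeast)
-------------------------------
Four state variables: total cyclin B (``CycB``, every cyclin molecule is
bound to the excess Cdk1, so total cyclin equals total MPF), active MPF
(``MPF``; the inactive, Tyr15-phosphorylated pool is ``CycB - MPF``),
and the active fractions of the regulators ``Wee1`` and ``Cdc25``
(totals normalised to 1). Following the Novák–Tyson formulation:

    dCycB/dt  = kS - kd*CycB
    dMPF/dt   = kS - kd*MPF - Vwee*MPF + V25*(CycB - MPF)
    Vwee      = kwee' *(1 - Wee1)  + kwee''*Wee1
    V25       = k25'  *(1 - Cdc25) + k25'' *Cdc25
    dWee1/dt  = kawee*(1-Wee1)/(Jawee + 1 - Wee1)
                - kiwee*MPF*Wee1/(Jiwee + Wee1)
    dCdc25/dt = ka25*(1-Cdc25)*MPF/(Ja25 + MPF)
                - ki25*Cdc25/(Ji25 + Cdc25)

Wee1 phosphorylation by MPF uses a Michaelis constant in the substrate
(Wee1), Cdc25 phosphorylation by MPF a Michaelis constant in MPF itself;
both readings of "the Michaelis constant of MPF" occur in the modelling
literature, and this combination is the one that reproduces the published
control coefficients for the degradation and Michaelis channels
simultaneously (see docs/methods.md). Time and concentrations are
dimensionless.

Reduced MAPK cascade (human)
----------------------------
Nine species (inactive/active pairs for Ras, Raf, Mek, Erk plus the
Shc-Grb2-Sos adaptor pool), twelve rate constants ``c1..c12``,
concentrations in molecules/cell, time in minutes. Activation flows
ShcGS -> Ras -> Raf -> Mek -> Erk; active Erk feeds back by degrading
the adaptor pool (c12), which shuts the cascade down and makes the
wild-type Erk* response a transient pulse. Each tier only interconverts
its active and inactive forms, so Ras, Raf, Mek and Erk totals are
conserved along any trajectory.
"""

from __future__ import annotations

import json
import pathlib

import yaml

from .errors import ValidationError
from .model import OdeModel

__all__ = [
    "g2m_model",
    "mapk_model",
    "linear_decay_model",
    "list_models",
    "get_model",
    "load_model_variant",
    "save_model_config",
    "G2M_WEE1_CHANNELS",
    "G2M_CDC25_CHANNELS",
]

# ---------------------------------------------------------------------------
# G2-M transition
# ---------------------------------------------------------------------------

G2M_PARAMS = {
    "k_S": 0.2, "k_d": 0.008,
    "k25p": 0.008, "k25pp": 0.89, "kweep": 0.03, "kweepp": 0.18,
    "k_awee": 0.61, "k_iwee": 0.71, "k_a25": 0.80, "k_i25": 0.35,
    "J_awee": 0.90, "J_iwee": 0.21, "J_a25": 0.19, "J_i25": 0.93,
}

G2M_INITIAL = {"CycB": 0.01, "MPF": 0.01, "Wee1": 1.0, "Cdc25": 0.01}

#: default horizon (dimensionless time); the wild type crosses MPF = 2.0
#: near t = 10.94, so 50 leaves ample room for perturbed variants.
G2M_HORIZON = 50.0

G2M_CHANNELS = (
    "cycb_synthesis",        # kS (appears in both CycB and MPF equations)
    "cycb_degradation",      # kd * CycB term
    "mpf_degradation",       # kd * MPF term
    "mpf_inhibition_basal",  # kwee' * (1 - Wee1) part of Vwee
    "mpf_inhibition_wee1",   # kwee'' * Wee1 part of Vwee
    "mpf_activation_basal",  # k25' * (1 - Cdc25) part of V25
    "mpf_activation_cdc25",  # k25'' * Cdc25 part of V25
    "wee1_activation",       # kawee term (phosphatase)
    "wee1_inactivation",     # kiwee term (MPF)
    "cdc25_activation",      # ka25 term (MPF)
    "cdc25_inactivation",    # ki25 term (phosphatase)
    "J_awee", "J_iwee", "J_a25", "J_i25",   # Michaelis-constant scalings
)

#: channel groups used for the Wee1 vs Cdc25 asymmetry comparison
G2M_WEE1_CHANNELS = (
    "mpf_inhibition_basal", "mpf_inhibition_wee1",
    "wee1_activation", "wee1_inactivation", "J_awee", "J_iwee",
)
G2M_CDC25_CHANNELS = (
    "mpf_activation_basal", "mpf_activation_cdc25",
    "cdc25_activation", "cdc25_inactivation", "J_a25", "J_i25",
)


def _g2m_rhs(p, m):
    # effective (channel-scaled) constants are hoisted out of the closure:
    # the RHS is the integrator hot loop
    syn = m["cycb_synthesis"] * p["k_S"]
    kd_cycb = m["cycb_degradation"] * p["k_d"]
    kd_mpf = m["mpf_degradation"] * p["k_d"]
    kweep = m["mpf_inhibition_basal"] * p["kweep"]
    kweepp = m["mpf_inhibition_wee1"] * p["kweepp"]
    k25p = m["mpf_activation_basal"] * p["k25p"]
    k25pp = m["mpf_activation_cdc25"] * p["k25pp"]
    kawee, kiwee = p["k_awee"], p["k_iwee"]
    ka25, ki25 = p["k_a25"], p["k_i25"]
    Jawee = m["J_awee"] * p["J_awee"]
    Jiwee = m["J_iwee"] * p["J_iwee"]
    Ja25 = m["J_a25"] * p["J_a25"]
    Ji25 = m["J_i25"] * p["J_i25"]

    def rhs(t, y):
        CycB, MPF, Wee1, Cdc25 = y
        Vwee = kweep * (1.0 - Wee1) + kweepp * Wee1
        V25 = k25p * (1.0 - Cdc25) + k25pp * Cdc25
        dCycB = syn - kd_cycb * CycB
        dMPF = syn - kd_mpf * MPF - Vwee * MPF + V25 * (CycB - MPF)
        dWee1 = (kawee * (1.0 - Wee1) / (Jawee + 1.0 - Wee1)
                 - kiwee * MPF * Wee1 / (Jiwee + Wee1))
        dCdc25 = (ka25 * (1.0 - Cdc25) * MPF / (Ja25 + MPF)
                  - ki25 * Cdc25 / (Ji25 + Cdc25))
        return [dCycB, dMPF, dWee1, dCdc25]

    return rhs


def g2m_model(params=None, initial_conditions=None, horizon=None) -> OdeModel:
    """The fission-yeast G2-M transition model with the published constants."""
    model = OdeModel(
        name="g2m",
        species=("CycB", "MPF", "Wee1", "Cdc25"),
        params=G2M_PARAMS,
        initial_conditions=G2M_INITIAL,
        horizon=G2M_HORIZON,
        channels=G2M_CHANNELS,
        rhs_factory=_g2m_rhs,
        provenance="Novak-Tyson-type G2-M switch, published reduced form",
    )
    if params or initial_conditions or horizon:
        model = model.with_updates(params=params,
                                   initial_conditions=initial_conditions,
                                   horizon=horizon)
    return model


# ---------------------------------------------------------------------------
# Reduced MAPK cascade
# ---------------------------------------------------------------------------

MAPK_PARAMS = {
    "c1": 69.0, "c2": 7.7e-4, "c3": 14.0, "c4": 50.0, "c5": 0.78,
    "c6": 8.3, "c7": 9e4, "c8": 4e5, "c9": 6e5, "c10": 15.0,
    "c11": 1.53e3, "c12": 4e-6,
}

MAPK_INITIAL = {
    "ShcGS": 20000.0, "RasGDP": 20000.0, "RasGTP": 0.0,
    "Raf": 10000.0, "Raf*": 0.0, "Mek": 360000.0, "Mek*": 0.0,
    "Erk": 750000.0, "Erk*": 0.0,
}

MAPK_HORIZON = 100.0  # minutes; covers the transient Erk* pulse

MAPK_CHANNELS = (
    "ras_activation",     # c1/c2 term (ShcGS-catalysed RasGDP -> RasGTP)
    "ras_inactivation",   # c3
    "raf_activation",     # c4
    "raf_inactivation",   # c5
    "mek_activation",     # c6
    "mek_inactivation",   # c7
    "erk_activation",     # c8/c9
    "erk_inactivation",   # c10/c11
    "erk_feedback",       # c12 (Erk* inhibits ShcGS)
)


def _mapk_rhs(p, m):
    c1 = m["ras_activation"] * p["c1"]
    c2 = p["c2"]
    c3 = m["ras_inactivation"] * p["c3"]
    c4 = m["raf_activation"] * p["c4"]
    c5 = m["raf_inactivation"] * p["c5"]
    c6 = m["mek_activation"] * p["c6"]
    c7 = m["mek_inactivation"] * p["c7"]
    c8 = m["erk_activation"] * p["c8"]
    c9 = p["c9"]
    c10 = m["erk_inactivation"] * p["c10"]
    c11 = p["c11"]
    c12 = m["erk_feedback"] * p["c12"]

    def rhs(t, y):
        Shc, RasGDP, RasGTP, Raf, Rafs, Mek, Meks, Erk, Erks = y
        ras_t = RasGDP + RasGTP
        mek_t = Mek + Meks
        v_ras_a = c1 * Shc * RasGDP / (c2 + RasGDP)
        v_ras_d = c3 * RasGTP
        v_raf_a = c4 * (RasGTP / ras_t) * Raf
        v_raf_d = c5 * Rafs
        v_mek_a = c6 * Rafs * Mek
        v_mek_d = c7 * Meks
        v_erk_a = c8 * (Meks / mek_t) * Erk / (c9 + Erk)
        v_erk_d = c10 * Erks / (1.0 + Erks / c11)
        v_fb = c12 * Erks * Shc
        return [
            -v_fb,
            -v_ras_a + v_ras_d,
            v_ras_a - v_ras_d,
            -v_raf_a + v_raf_d,
            v_raf_a - v_raf_d,
            -v_mek_a + v_mek_d,
            v_mek_a - v_mek_d,
            -v_erk_a + v_erk_d,
            v_erk_a - v_erk_d,
        ]

    return rhs


def mapk_model(params=None, initial_conditions=None, horizon=None) -> OdeModel:
    """The reduced human MAPK cascade with the published constants."""
    model = OdeModel(
        name="mapk_reduced",
        species=("ShcGS", "RasGDP", "RasGTP", "Raf", "Raf*",
                 "Mek", "Mek*", "Erk", "Erk*"),
        params=MAPK_PARAMS,
        initial_conditions=MAPK_INITIAL,
        horizon=MAPK_HORIZON,
        channels=MAPK_CHANNELS,
        rhs_factory=_mapk_rhs,
        provenance="12-parameter reduction of the Brightman-Fell EGF cascade",
    )
    if params or initial_conditions or horizon:
        model = model.with_updates(params=params,
                                   initial_conditions=initial_conditions,
                                   horizon=horizon)
    return model


# ---------------------------------------------------------------------------
# Toy model used for closed-form sensitivity checks
# ---------------------------------------------------------------------------

def _linear_decay_rhs(p, m):
    def rhs(t, y):
        return [-m["decay"] * p["k"] * y[0], 0.0 * y[1]]
    return rhs


def linear_decay_model(k=0.3, s0=1.0, horizon=10.0) -> OdeModel:
    """``ds/dt = -k s`` with a channel on the decay term.

    ``s(T) = s0 * exp(-kT)`` gives closed-form control coefficients, which
    makes this the oracle model for finite-difference consistency tests.
    The second species ``dead`` sits on a zero-rate term behind the
    ``dead_term`` channel and never moves.
    """
    return OdeModel(
        name="linear_decay",
        species=("s", "dead"),
        params={"k": float(k), "k_zero": 0.0},
        initial_conditions={"s": float(s0), "dead": 0.0},
        horizon=float(horizon),
        channels=("decay", "dead_term"),
        rhs_factory=lambda p, m: (lambda t, y: [
            -m["decay"] * p["k"] * y[0],
            m["dead_term"] * p["k_zero"] * y[0],
        ]),
        provenance="analytic test model",
    )


# ---------------------------------------------------------------------------
# Catalog and config IO
# ---------------------------------------------------------------------------

_CATALOG = {
    "g2m": g2m_model,
    "mapk_reduced": mapk_model,
}


def list_models():
    """Catalog entries as (key, provenance) pairs."""
    return [(key, fn().provenance) for key, fn in sorted(_CATALOG.items())]


def get_model(key: str) -> OdeModel:
    try:
        return _CATALOG[key]()
    except KeyError:
        raise ValidationError(
            f"unknown model key {key!r}; available: {sorted(_CATALOG)}"
        ) from None


def save_model_config(model: OdeModel, path):
    """Write a model's numeric description as YAML (or JSON by suffix)."""
    cfg = model.to_config()
    path = pathlib.Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_model_variant(path) -> OdeModel:
    """Build a model variant from a YAML/JSON config.

    The config must name a built-in ``family`` (the structure/equations)
    and provide the full ``params`` and ``initial_conditions`` inventories
    of that family; missing or unknown names fail validation with the
    offending field spelled out.
    """
    path = pathlib.Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} is empty or not a mapping")
    family = cfg.get("family")
    if family not in _CATALOG:
        raise ValidationError(
            f"config {path} must set 'family' to one of {sorted(_CATALOG)}")
    ref = _CATALOG[family]()
    for section, reference in (("params", ref.params),
                               ("initial_conditions", ref.initial_conditions)):
        given = cfg.get(section)
        if given is None:
            raise ValidationError(f"config {path} is missing '{section}'")
        missing = set(reference) - set(given)
        if missing:
            raise ValidationError(
                f"config {path} section '{section}' is missing "
                f"{sorted(missing)}")
        unknown = set(given) - set(reference)
        if unknown:
            raise ValidationError(
                f"config {path} section '{section}' has unknown entries "
                f"{sorted(unknown)}")
    species = cfg.get("species")
    if species is not None and tuple(species) != ref.species:
        raise ValidationError(
            f"config {path} species {species} do not match family "
            f"{family!r} species {list(ref.species)}")
    return ref.with_updates(params=cfg["params"],
                            initial_conditions=cfg["initial_conditions"],
                            horizon=cfg.get("horizon"))
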