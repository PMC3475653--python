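"""Normalized control coefficients and sensitivity sweeps.

The control coefficient of a scalar readout ``S`` with respect to a
perturbation spec is the relative/relative sensitivity

    C = ((S' - S) / S) / delta

where ``S'`` is the readout after scaling each channel in the spec by
``1 + weight * delta``. A positive coefficient means the readout rises
under a positive perturbation. The default is a one-sided forward
difference at the working perturbation size ``delta = 0.1`` (i.e. a
total 10% relative perturbation, split across channels by weight); a
central difference is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import NoCrossingError, ReadoutError, SifkitError, ValidationError
from .metrics import g2m_readout, mapk_metrics
from .model import OdeModel, PerturbationSpec, apply_perturbation, integrate

__all__ = [
    "ControlCoefficient",
    "control_coefficient",
    "g2m_mutation_specs",
    "mapk_control_vector",
    "sensitivity_sweep",
    "MAPK_METRIC_NAMES",
]

MAPK_METRIC_NAMES = ("amplitude", "duration", "peak_time")


@dataclass(frozen=True)
class ControlCoefficient:
    """A signed, dimensionless sensitivity of one readout to one spec."""

    spec: PerturbationSpec
    readout: str
    value: float
    censored: bool = False

    def __post_init__(self):
        if not self.censored and not np.isfinite(self.value):
            raise ValidationError(
                f"non-finite control coefficient for {self.readout!r} "
                f"under spec {self.spec.label!r}")


def control_coefficient(model: OdeModel, readout_fn: Callable[[OdeModel], float],
                        spec: PerturbationSpec, *, central=False,
                        wild_type_value=None) -> ControlCoefficient:
    """Forward-difference control coefficient of ``readout_fn``.

    ``wild_type_value`` can be supplied to avoid recomputing the baseline
    across many specs. Readout failures on the perturbed model are
    re-raised as :class:`ReadoutError` carrying the spec label.
    """
    if spec.delta <= 0:
        raise ValidationError("control_coefficient needs delta > 0")
    S = readout_fn(model) if wild_type_value is None else wild_type_value
    if S == 0:
        raise ReadoutError("wild-type readout is zero; coefficient undefined",
                           label=spec.label)

    def _perturbed(sign):
        if sign > 0:
            pmodel = apply_perturbation(model, spec)
        else:
            mults = {c: 1.0 - w * spec.delta for c, w in spec.components}
            pmodel = model.with_updates(multipliers={
                c: model.channel_multipliers[c] * m for c, m in mults.items()})
        try:
            return readout_fn(pmodel)
        except SifkitError as exc:
            raise ReadoutError(
                f"readout failed on perturbed model: {exc}",
                label=spec.label) from exc

    if central:
        Sp, Sm = _perturbed(+1), _perturbed(-1)
        value = ((Sp - Sm) / S) / (2.0 * spec.delta)
    else:
        Sp = _perturbed(+1)
        value = ((Sp - S) / S) / spec.delta
    return ControlCoefficient(spec=spec, readout=getattr(readout_fn, "__name__",
                                                         "readout"),
                              value=float(value))


def g2m_mutation_specs(delta=0.1, j_wee_channel="J_iwee",
                       j_25_channel="J_a25") -> dict:
    """The three composite perturbation specs used for the G2-M mutations.

    * ``kd_CycB``: cyclin-degradation composite, 0.3 on the monomeric
      cyclin-degradation term and 0.7 on the MPF-degradation term.
    * ``kd_Cdk1``: MPF degradation only (total Cdk1 is constant, so Cdk1
      turnover acts through the complex).
    * ``J_combined``: the MPF Michaelis constants, 0.9 on the Wee1-side
      constant and 0.1 on the Cdc25-side constant. The mapping of the two
      published symbols onto the four Michaelis constants defaults to
      ``J_iwee``/``J_a25`` (MPF acting on Wee1 and Cdc25) and is
      overridable.
    """
    return {
        "kd_CycB": PerturbationSpec(
            (("cycb_degradation", 0.3), ("mpf_degradation", 0.7)),
            delta=delta, label="kd_CycB"),
        "kd_Cdk1": PerturbationSpec(
            (("mpf_degradation", 1.0),), delta=delta, label="kd_Cdk1"),
        "J_combined": PerturbationSpec(
            ((j_wee_channel, 0.9), (j_25_channel, 0.1)),
            delta=delta, label="J_combined"),
    }


def mapk_control_vector(model: OdeModel, spec: PerturbationSpec,
                        reporter: str = "Erk*",
                        wild_type_metrics=None) -> dict:
    """Control coefficients of amplitude, duration and peak time.

    Each component is normalized by its wild-type value and by ``delta``.
    A censored duration (signal never falls to half-maximum) yields a
    flagged, NaN-valued coefficient rather than a silent number.
    """
    if spec.delta <= 0:
        raise ValidationError("mapk_control_vector needs delta > 0")
    wt = (wild_type_metrics if wild_type_metrics is not None
          else mapk_metrics(integrate(model), reporter))
    pm = mapk_metrics(integrate(apply_perturbation(model, spec)), reporter)
    out = {}
    for name in MAPK_METRIC_NAMES:
        w, p = getattr(wt, name), getattr(pm, name)
        censored = (wt.censored or pm.censored) and name == "duration"
        if censored:
            value = float("nan")
        elif w == 0:
            value = float("nan")
            censored = True
        else:
            value = ((p - w) / w) / spec.delta
        out[name] = ControlCoefficient(spec=spec, readout=name,
                                       value=value, censored=censored)
    return out


def _default_readouts(model: OdeModel):
    if "MPF" in model.species:
        return {"cycb_at_entry": lambda m: g2m_readout(m)}
    if "Erk*" in model.species:
        return None  # signals the three-metric path
    raise ValidationError(
        f"no default readout for model {model.name!r}; pass readout_fn")


def sensitivity_sweep(model: OdeModel, targets, *, delta=0.1,
                      readout_fn=None, reporter="Erk*") -> pd.DataFrame:
    """Control coefficients for a list of channels / initial conditions.

    ``targets`` may contain channel names or ``init:<species>`` entries;
    each becomes a single-component spec at the given ``delta``. Rows are
    emitted in input order; per-target failures are recorded in the
    ``error`` column and the sweep continues.
    """
    targets = list(targets)
    rows = []
    multi = readout_fn is None and "Erk*" in model.species
    if multi:
        wt = mapk_metrics(integrate(model), reporter)
    else:
        readouts = ({"readout": readout_fn} if readout_fn is not None
                    else _default_readouts(model))
        name, fn = next(iter(readouts.items()))
        wt_value = fn(model)

    for target in targets:
        row = {"model": model.name, "target": target, "delta": delta,
               "error": ""}
        try:
            if target.startswith("init:"):
                species = target[5:]
                if species not in model.species:
                    raise ValidationError(
                        f"unknown species {species!r} in target {target!r}")
                base = model.initial_conditions[species]
                pmodel = model.with_updates(
                    initial_conditions={species: base * (1.0 + delta)})
            elif target in model.channels:
                spec = PerturbationSpec(((target, 1.0),), delta=delta,
                                        label=target)
                pmodel = apply_perturbation(model, spec)
            else:
                raise ValidationError(
                    f"target {target!r} is neither a channel nor "
                    f"'init:<species>' of model {model.name!r}")
            if multi:
                pm = mapk_metrics(integrate(pmodel), reporter)
                for mname in MAPK_METRIC_NAMES:
                    w, p = getattr(wt, mname), getattr(pm, mname)
                    if (wt.censored or pm.censored) and mname == "duration":
                        row["C_" + mname] = float("nan")
                        row["error"] = "censored duration"
                    else:
                        row["C_" + mname] = ((p - w) / w) / delta
            else:
                S = fn(pmodel)
                row["C_" + name] = ((S - wt_value) / wt_value) / delta
        except SifkitError as exc:
            row["error"] = str(exc)
        rows.append(row)

    columns = ["model", "target", "delta"]
    columns += (["C_" + n for n in MAPK_METRIC_NAMES] if multi
                else ["C_" + name])
    columns.append("error")
    return pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(
        columns=columns)
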