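"""Systemic impact factors: ddG x control coefficient.

A mutation's systemic impact factor (SIF) combines how much it
destabilises its protein (ddG, kcal/mol) with how sensitive the pathway
readout is to the rate constants that the mutation perturbs (the control
coefficient of the mapped perturbation spec):

    SIF = max_ddG * C                  (linear, the published form)
    SIF = lambda_class * max_ddG * C   (lambda variant; per-class scale)
    SIF = C * exp(max_ddG / RT)        (exponential variant, provisional)

For the G2-M system a mutation yields one score; for the MAPK cascade it
yields three (amplitude / duration / peak-time components of the Erk*
response). Two scoring paths exist: "table" (control coefficients
supplied, pure arithmetic) and "model" (coefficients computed from the
ODE model), so arithmetic can be verified independently of any ODE
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datasets import load_mapk_mapping
from .ddg import (DEFAULT_TEMPERATURE, GAS_CONSTANT_KCAL, MutationRecord,
                  ddg_stderr, max_ddg)
from .errors import MappingError, SifkitError, ValidationError
from .metrics import mapk_metrics
from .model import OdeModel, PerturbationSpec, integrate
from .sensitivity import (MAPK_METRIC_NAMES, control_coefficient,
                          g2m_mutation_specs, mapk_control_vector)
from .metrics import g2m_readout

__all__ = ["SifScore", "map_mutation", "sif_score", "batch_score",
           "sif_trajectory_grouping", "table_c_from_fixture", "TRANSFORMS"]

TRANSFORMS = ("linear", "lambda", "exp")

#: RT in kcal/mol at the 298 K evaluation temperature
RT_KCAL = GAS_CONSTANT_KCAL * DEFAULT_TEMPERATURE

#: built-in G2-M mapping rules: (protein, impact class) -> spec label
_G2M_RULES = {
    ("Cdk1", "F"): "J_combined",
    ("Cdk1", "S"): "kd_Cdk1",
    ("CycB", "S"): "kd_CycB",
}


@dataclass(frozen=True)
class SifScore:
    """Scored mutation: one (G2-M) or three (MAPK) components."""

    mutation: MutationRecord
    components: Mapping[str, float]
    stderr: Optional[Mapping[str, float]] = None
    transform: str = "linear"
    spec_label: str = ""


def map_mutation(record: MutationRecord, model_key: str, *, mapping=None,
                 delta=0.1) -> PerturbationSpec:
    """Perturbation spec targeted by a mutation.

    G2-M rules are built in: functional Cdk1 mutations perturb the MPF
    Michaelis constants (0.9/0.1 composite), structural Cdk1 mutations
    the MPF degradation term, structural CycB mutations the 0.3/0.7
    cyclin/MPF degradation composite. MAPK mutations are routed through a
    user-editable protein/class -> channel table (the packaged default is
    a synthetic stand-in).
    """
    key = (record.protein, record.impact_class)
    if model_key == "g2m":
        label = _G2M_RULES.get(key)
        if label is None:
            raise MappingError(
                f"no G2-M rule for protein/class {key}; known pairs: "
                f"{sorted(_G2M_RULES)}")
        return g2m_mutation_specs(delta=delta)[label]
    if model_key == "mapk_reduced":
        table = load_mapk_mapping() if mapping is None else mapping
        hit = table[(table["protein"] == record.protein)
                    & (table["impact_class"] == record.impact_class)]
        if hit.empty:
            known = sorted(map(tuple, table[["protein", "impact_class"]]
                               .itertuples(index=False)))
            raise MappingError(
                f"no mapping-table entry for protein/class {key}; "
                f"known pairs: {known}")
        row = hit.iloc[0]
        channels = [c.strip() for c in str(row["channels"]).split(",")]
        weights = [float(w) for w in str(row["weights"]).split(",")]
        if len(channels) != len(weights):
            raise ValidationError(
                f"mapping row for {key} has {len(channels)} channels but "
                f"{len(weights)} weights")
        return PerturbationSpec(tuple(zip(channels, weights)), delta=delta,
                                label=f"{record.protein}:{record.impact_class}")
    raise ValidationError(f"unknown model key {model_key!r}")


def _transform_value(ddg, c, transform, lam):
    if transform == "linear":
        return ddg * c
    if transform == "lambda":
        return lam * ddg * c
    if transform == "exp":
        # provisional exponential variant: the perturbation scales like a
        # Boltzmann factor of the stability change
        return c * math.exp(ddg / RT_KCAL)
    raise ValidationError(f"unknown transform {transform!r}; "
                          f"choose from {TRANSFORMS}")


def _transform_stderr(ddg, c, se_ddg, transform, lam):
    if transform == "linear":
        return abs(c) * se_ddg
    if transform == "lambda":
        return abs(lam * c) * se_ddg
    if transform == "exp":
        return abs(c) * math.exp(ddg / RT_KCAL) * se_ddg / RT_KCAL
    raise ValidationError(f"unknown transform {transform!r}")


def sif_score(record: MutationRecord, coefficients, *, transform="linear",
              lambda_f=1.0, lambda_s=1.0, spec_label="") -> SifScore:
    """Combine a mutation's max ddG with control coefficient(s).

    ``coefficients`` is a single value/ControlCoefficient (G2-M) or a
    mapping metric -> value/ControlCoefficient (MAPK). Component values
    are ``transform(max_ddG) x C``; standard errors are present iff the
    record carries a conformational ensemble (the spread of the ensemble
    propagated through the transform).
    """
    ddg = max_ddg(record)
    lam = lambda_f if record.impact_class == "F" else lambda_s
    if not isinstance(coefficients, Mapping):
        coefficients = {"sif": coefficients}
    comps, errs = {}, {}
    se_ddg = (ddg_stderr(record.ddg_ensemble)
              if record.ddg_ensemble and len(record.ddg_ensemble) >= 2
              else None)
    for name, c in coefficients.items():
        value = getattr(c, "value", c)
        if value is None or not np.isfinite(value):
            raise ValidationError(
                f"missing/censored coefficient {name!r} for "
                f"{record.residue_change}")
        comps[name] = _transform_value(ddg, float(value), transform, lam)
        if se_ddg is not None:
            errs[name] = _transform_stderr(ddg, float(value), se_ddg,
                                           transform, lam)
    return SifScore(mutation=record, components=comps,
                    stderr=errs or None, transform=transform,
                    spec_label=spec_label)


def table_c_from_fixture(df: pd.DataFrame) -> dict:
    """Published control coefficients keyed by residue change.

    Picks, per row, the single non-empty entry among the three published
    coefficient columns of the G2-M fixture table.
    """
    out = {}
    cols = ["c_kd_cycb", "c_kd_cdk1", "c_j_combined"]
    for _, row in df.iterrows():
        vals = [(c, row[c]) for c in cols
                if str(row[c]).strip() not in ("-", "", "nan")]
        if len(vals) != 1:
            raise ValidationError(
                f"fixture row {row['residue_change']} must have exactly one "
                f"published coefficient, found {len(vals)}")
        out[row["residue_change"]] = float(vals[0][1])
    return out


def batch_score(records, *, model_key="g2m", c_source="model", model=None,
                c_values=None, mapping=None, transform="linear",
                lambda_f=1.0, lambda_s=1.0, delta=0.1) -> pd.DataFrame:
    """Score a mutation table; one row per mutation, input order kept.

    ``c_source='model'`` computes coefficients from the ODE model (one
    integration per distinct perturbation spec); ``c_source='table'``
    takes them from ``c_values`` (mapping residue_change -> value or
    metric->value mapping), the pure-arithmetic path. Mapping failures
    are collected per row in the ``error`` column and scoring continues.
    """
    records = list(records)
    multi = model_key == "mapk_reduced"
    if c_source == "model":
        if model is None:
            from .models_builtin import get_model
            model = get_model(model_key)
        cache = {}
        if multi:
            wt_metrics = mapk_metrics(integrate(model))
        else:
            wt_value = g2m_readout(model)

    rows = []
    for rec in records:
        row = {"protein": rec.protein, "residue_change": rec.residue_change,
               "impact_class": rec.impact_class, "spec_label": "",
               "error": ""}
        try:
            row["max_ddg"] = max_ddg(rec)
            if c_source == "table":
                if c_values is None or rec.residue_change not in c_values:
                    raise MappingError(
                        f"no supplied coefficient for {rec.residue_change}")
                coeffs = c_values[rec.residue_change]
                if not isinstance(coeffs, Mapping) and multi:
                    raise ValidationError(
                        "MAPK table scoring needs one value per metric")
            else:
                spec = map_mutation(rec, model_key, mapping=mapping,
                                    delta=delta)
                row["spec_label"] = spec.label
                if spec.label not in cache:
                    if multi:
                        cache[spec.label] = mapk_control_vector(
                            model, spec, wild_type_metrics=wt_metrics)
                    else:
                        cache[spec.label] = control_coefficient(
                            model, g2m_readout, spec,
                            wild_type_value=wt_value)
                coeffs = cache[spec.label]
            score = sif_score(rec, coeffs, transform=transform,
                              lambda_f=lambda_f, lambda_s=lambda_s,
                              spec_label=row["spec_label"])
            if multi:
                for name in MAPK_METRIC_NAMES:
                    c = coeffs[name]
                    row["C_" + name] = float(getattr(c, "value", c))
                    row["sif_" + name] = score.components[name]
                    if score.stderr:
                        row["stderr_" + name] = score.stderr[name]
            else:
                c = coeffs["sif"] if isinstance(coeffs, Mapping) else coeffs
                row["C"] = float(getattr(c, "value", c))
                row["sif"] = score.components["sif"]
                if score.stderr:
                    row["stderr"] = score.stderr["sif"]
        except SifkitError as exc:
            row["error"] = str(exc)
        rows.append(row)

    base = ["protein", "residue_change", "impact_class", "max_ddg",
            "spec_label"]
    if multi:
        cols = base + ["C_" + n for n in MAPK_METRIC_NAMES] \
            + ["sif_" + n for n in MAPK_METRIC_NAMES]
        if any("stderr_amplitude" in r for r in rows):
            cols += ["stderr_" + n for n in MAPK_METRIC_NAMES]
    else:
        cols = base + ["C", "sif"]
        if any("stderr" in r for r in rows):
            cols.append("stderr")
    cols.append("error")
    return pd.DataFrame(rows, columns=cols)


def sif_trajectory_grouping(score_table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein dominance summary of three-component scores.

    For each protein, the mean |SIF| of each component is expressed as a
    share of their sum; ``dominant`` names the component with the largest
    share. Used to ask whether mutations in one protein perturb the Erk
    response along a different axis than mutations elsewhere.
    """
    comp_cols = ["sif_" + n for n in MAPK_METRIC_NAMES]
    missing = set(comp_cols) - set(score_table.columns)
    if missing:
        raise ValidationError(
            f"score table lacks 3-component columns {sorted(missing)}")
    rows = []
    for protein, grp in score_table.groupby("protein", sort=False):
        means = {n: float(np.nanmean(np.abs(grp["sif_" + n])))
                 for n in MAPK_METRIC_NAMES}
        total = sum(means.values())
        shares = {n: (means[n] / total if total > 0 else np.nan)
                  for n in MAPK_METRIC_NAMES}
        dominant = max(means, key=means.get) if total > 0 else ""
        rows.append({"protein": protein,
                     **{"share_" + n: shares[n] for n in MAPK_METRIC_NAMES},
                     "dominant": dominant, "n_mutations": len(grp)})
    return pd.DataFrame(rows)
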