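"""Per-mutation free-energy changes: state selection and ensemble averages.

A missense mutation can destabilise a protein in its uncomplexed state,
its complexed state, or both; the score used downstream takes the
*maximum* over the states present, which keeps mutations comparable
whether one or two states were evaluated. When an ensemble of
conformations was sampled, the ensemble mean is a Boltzmann-Gibbs
weighted average: lower-energy (less destabilised) conformations receive
more weight, ``w_i ~ exp(-ddG_i / (k_B T))``.

ddG values are inputs here (kcal/mol); computing them from structures is
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MutationRecord", "DdgSummary", "max_ddg", "boltzmann_average",
           "ddg_stderr", "summarize", "read_mutations", "write_mutations",
           "GAS_CONSTANT_KCAL", "DEFAULT_TEMPERATURE"]

#: gas constant in kcal/(mol K); temperatures in Kelvin
GAS_CONSTANT_KCAL = 1.987204259e-3
#: evaluation temperature for free-energy averaging (K)
DEFAULT_TEMPERATURE = 298.0

IMPACT_CLASSES = ("F", "S")


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation with per-state free-energy changes.

    ``impact_class`` is 'F' (functional: at/near the active site,
    perturbs interaction constants) or 'S' (structural: elsewhere,
    perturbs stability/degradation-linked constants); the classification
    is an input, made by structural inspection. ``residue_change`` uses
    the one-letter "<wt><position><mutant>" convention, e.g. ``G43E``.
    """

    protein: str
    residue_change: str
    impact_class: str
    ddg_monomer: Optional[float] = None
    ddg_complex: Optional[float] = None
    ddg_ensemble: Optional[tuple] = None

    def __post_init__(self):
        if self.impact_class not in IMPACT_CLASSES:
            raise ValidationError(
                f"impact_class must be one of {IMPACT_CLASSES}, got "
                f"{self.impact_class!r} for {self.residue_change}")
        if self.ddg_monomer is None and self.ddg_complex is None:
            raise ValidationError(
                f"mutation {self.residue_change}: at least one of "
                "ddg_monomer/ddg_complex must be present")
        if self.ddg_ensemble is not None:
            object.__setattr__(self, "ddg_ensemble",
                               tuple(float(x) for x in self.ddg_ensemble))


@dataclass(frozen=True)
class DdgSummary:
    """Maximum-over-states and ensemble statistics for one mutation."""

    max_ddg: float
    mean_ddg: float
    stderr: float
    stderr_defined: bool = True


def max_ddg(record: MutationRecord) -> float:
    """Maximum ddG over the states present (complexed / uncomplexed)."""
    states = [x for x in (record.ddg_monomer, record.ddg_complex)
              if x is not None]
    if not states:
        raise ValidationError(
            f"mutation {record.residue_change} has no ddG values")
    return float(max(states))


def boltzmann_average(ensemble: Sequence[float],
                      temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Boltzmann-Gibbs weighted mean of an ensemble of ddG values.

    Weights are proportional to ``exp(-ddG_i / (k_B T))`` (normalised),
    so the average is pulled toward the lower-energy conformations and is
    never larger than the arithmetic mean; as T grows the weights flatten
    and the arithmetic mean is recovered.
    """
    e = np.asarray(list(ensemble), float)
    if e.size == 0:
        raise ValidationError("ensemble must be non-empty")
    if temperature <= 0:
        raise ValidationError("temperature must be positive (Kelvin)")
    beta = 1.0 / (GAS_CONSTANT_KCAL * temperature)
    # shift for numerical stability; weights are shift-invariant
    w = np.exp(-beta * (e - e.min()))
    return float(np.sum(w * e) / np.sum(w))


def ddg_stderr(ensemble: Sequence[float]) -> float:
    """Standard error of the ensemble mean (unweighted, ddof=1).

    The published error bars derive from the ddG evaluation over sampled
    conformations; whether they weight the variance is unstated, so the
    plain (unweighted) standard error of the mean is used and documented
    as an assumption. Ensembles smaller than two have no defined spread;
    see :func:`summarize`, which flags that case and reports zero.
    """
    e = np.asarray(list(ensemble), float)
    if e.size < 2:
        return 0.0
    return float(np.std(e, ddof=1) / math.sqrt(e.size))


def summarize(record: MutationRecord,
              temperature: float = DEFAULT_TEMPERATURE) -> DdgSummary:
    """Max-over-states plus ensemble mean/stderr for one mutation."""
    mx = max_ddg(record)
    if record.ddg_ensemble:
        mean = boltzmann_average(record.ddg_ensemble, temperature)
        n = len(record.ddg_ensemble)
        return DdgSummary(max_ddg=mx, mean_ddg=mean,
                          stderr=ddg_stderr(record.ddg_ensemble),
                          stderr_defined=n >= 2)
    return DdgSummary(max_ddg=mx, mean_ddg=mx, stderr=0.0,
                      stderr_defined=False)


# ---------------------------------------------------------------------------
# tabular IO (TSV with a header row; '-' or blank marks an absent state)
# ---------------------------------------------------------------------------

_COLUMNS = ["protein", "residue_change", "impact_class",
            "ddg_monomer", "ddg_complex", "ensemble"]


def _parse_float(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip().replace(",", "")
    if s in ("", "-", "NA", "nan"):
        return None
    return float(s)


def read_mutations(path) -> list:
    """Read a mutation table (TSV) into :class:`MutationRecord` rows.

    The optional ``ensemble`` column holds semicolon-separated ddG values
    from sampled conformations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValidationError(
            f"mutation table {path} is missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        ens = None
        if "ensemble" in df.columns:
            raw = row.get("ensemble")
            if isinstance(raw, str) and raw.strip() not in ("", "-"):
                ens = tuple(float(v) for v in raw.split(";"))
        records.append(MutationRecord(
            protein=str(row["protein"]).strip(),
            residue_change=str(row["residue_change"]).strip(),
            impact_class=str(row["impact_class"]).strip(),
            ddg_monomer=_parse_float(row.get("ddg_monomer")),
            ddg_complex=_parse_float(row.get("ddg_complex")),
            ddg_ensemble=ens,
        ))
    return records


def write_mutations(records, path):
    rows = []
    for r in records:
        rows.append({
            "protein": r.protein,
            "residue_change": r.residue_change,
            "impact_class": r.impact_class,
            "ddg_monomer": "-" if r.ddg_monomer is None else repr(r.ddg_monomer),
            "ddg_complex": "-" if r.ddg_complex is None else repr(r.ddg_complex),
            "ensemble": (";".join(repr(v) for v in r.ddg_ensemble)
                         if r.ddg_ensemble else "-"),
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
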