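"""Synthetic data generators.

Two generators make every other module testable without external data:

* :func:`generate_mutation_set` emulates a panel of disease-associated
  missense mutations spread over the four MAPK proteins, with impact
  classes and log-normally distributed ddG values — bulk between about
  0.5 and 10 kcal/mol, plus an occasional clash-scale outlier above
  20 kcal/mol of the kind produced when a mutation to a bulky side chain
  is scored against a rigid backbone.
* :func:`generate_reference_timecourse` samples a model trajectory at
  given times and adds i.i.d. Gaussian noise of known sigma, producing
  calibration data for the replica-exchange fitter.

All randomness flows from an explicit integer seed; identical seeds give
identical output.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import OdeModel, integrate

__all__ = ["SyntheticSpec", "generate_mutation_set",
           "generate_reference_timecourse", "MAPK_PROTEINS"]

MAPK_PROTEINS = ("H-Ras", "Raf-1", "B-Raf", "Mek")

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for a synthetic MAPK mutation panel.

    ``ddg_mu``/``ddg_sigma`` parametrise the log-normal bulk of the ddG
    distribution (kcal/mol, log scale); ``clash_fraction`` of mutations
    instead draw a clash-scale value uniform on
    [``clash_low``, ``clash_high``].
    """

    seed: int
    n_mutations: int = 40
    proteins: tuple = MAPK_PROTEINS
    ddg_mu: float = np.log(3.0)
    ddg_sigma: float = 0.75
    clash_fraction: float = 0.05
    clash_low: float = 20.0
    clash_high: float = 35.0
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.n_mutations < 1:
            raise ValidationError("n_mutations must be >= 1")
        if not (0 <= self.clash_fraction <= 1):
            raise ValidationError("clash_fraction must be in [0, 1]")


def _draw_ddg(rng, spec):
    if rng.random() < spec.clash_fraction:
        return float(rng.uniform(spec.clash_low, spec.clash_high))
    return float(np.exp(rng.normal(spec.ddg_mu, spec.ddg_sigma)))


def generate_mutation_set(spec: SyntheticSpec) -> pd.DataFrame:
    """A reproducible synthetic mutation table over the MAPK proteins.

    Every protein is represented (round-robin assignment, then shuffle);
    residue-change strings follow the one-letter wt/position/mutant
    convention; all ddG values are strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [spec.proteins[i % len(spec.proteins)]
                for i in range(spec.n_mutations)]
    rng.shuffle(proteins)
    rows = []
    seen = set()
    for protein in proteins:
        while True:
            wt, mut = rng.choice(list(_AA), size=2, replace=False)
            pos = int(rng.integers(2, 400))
            change = f"{wt}{pos}{mut}"
            if (protein, change) not in seen:
                seen.add((protein, change))
                break
        rows.append({
            "protein": protein,
            "residue_change": change,
            "impact_class": "F" if rng.random() < 0.5 else "S",
            "ddg_monomer": round(_draw_ddg(rng, spec), 3),
            "ddg_complex": "-",
            "ensemble": "-",
        })
    return pd.DataFrame(rows, columns=["protein", "residue_change",
                                       "impact_class", "ddg_monomer",
                                       "ddg_complex", "ensemble"])


def generate_reference_timecourse(model: OdeModel, times, *, noise_sigma,
                                  seed, species=None,
                                  overrides=None) -> pd.DataFrame:
    """Noisy observations of a model trajectory.

    Returns a long-format table (time, species, value, sigma) compatible
    with :func:`sifkit.remc.chisq_energy`. With ``noise_sigma = 0`` the
    exact model values are returned.
    """
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if times.max() > model.horizon:
        raise ValidationError("sample times exceed the model horizon")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be non-negative")
    traj = integrate(model, overrides=overrides)
    chosen = tuple(species) if species else model.species
    rng = np.random.default_rng(seed)
    rows = []
    for sp in chosen:
        clean = np.interp(times, traj.times, traj.value(sp))
        noisy = clean + rng.normal(0.0, noise_sigma, size=times.size) \
            if noise_sigma > 0 else clean
        for t, v in zip(times, noisy):
            rows.append({"time": float(t), "species": sp, "value": float(v),
                         "sigma": float(noise_sigma) if noise_sigma > 0
                         else 1.0})
    return pd.DataFrame(rows)
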