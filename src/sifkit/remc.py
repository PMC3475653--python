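"""Replica-exchange (parallel tempering) Monte Carlo parameter inference.

Several replicas of the model are sampled in parallel at different
inverse temperatures ``beta_m``; within each replica a Metropolis chain
moves one randomly chosen free parameter per iteration, and at regular
intervals a randomly chosen adjacent pair of replicas attempts to swap
parameter vectors. Hot replicas cross energy barriers that would trap a
cold chain, and the exchanges anneal good parameter sets down the ladder.

The energy of a parameter vector is the chi-squared deviation between
simulated and reference time courses: ``sum(((sim - obs)/sigma)^2)``.
Step sizes follow the mixed-scale law ``dx = s * d * 10^e`` with integer
``d ~ U{1..9}``, integer ``e ~ U{e_min..e_max}`` and ``s = +-1``
equiprobable, giving a proposal density sharply peaked near zero with
long tails. The swap probability for an adjacent pair is
``min(1, exp(dbeta * dE))`` with ``dbeta = beta_{m+1} - beta_m`` and
``dE = E_{m+1} - E_m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SifkitError, ValidationError
from .model import OdeModel, integrate

__all__ = ["ReplicaState", "REMCResult", "propose_step", "chisq_energy",
           "make_chisq_energy", "metropolis_accept", "swap_accept",
           "run_remc", "reference_frame"]


@dataclass
class ReplicaState:
    """One replica: parameter vector, inverse temperature, energy."""

    params: dict
    beta: float
    energy: float

    def __post_init__(self):
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        if self.energy < 0:
            raise ValidationError("energy must be non-negative")


@dataclass
class REMCResult:
    """Chains, best-fit parameters and swap statistics of one run."""

    chains: list            # per replica: DataFrame(iteration, energy, params)
    best_params: dict
    best_energy: float
    betas: tuple
    move_acceptance: tuple  # per replica acceptance rate
    swap_attempts: int
    swap_accepts: int

    @property
    def swap_rate(self):
        return self.swap_accepts / self.swap_attempts if self.swap_attempts else 0.0


def propose_step(rng, e_min=-4, e_max=-1):
    """One mixed-scale step ``s * d * 10^e`` (see module docstring)."""
    d = int(rng.integers(1, 10))
    e = int(rng.integers(e_min, e_max + 1))
    s = 1 if rng.random() < 0.5 else -1
    return s * d * 10.0 ** e


def reference_frame(times, values_by_species, sigma) -> pd.DataFrame:
    """Assemble a long-format reference table (time, species, value, sigma)."""
    rows = []
    for species, vals in values_by_species.items():
        for t, v in zip(times, vals):
            rows.append({"time": float(t), "species": species,
                         "value": float(v), "sigma": float(sigma)})
    return pd.DataFrame(rows)


def chisq_energy(model: OdeModel, params: Mapping[str, float],
                 reference: pd.DataFrame, *, rtol=1e-6, atol=1e-9) -> float:
    """Chi-squared deviation of the model (with ``params``) from reference.

    Integration failure is not an exception here: it returns ``inf`` so
    the Metropolis step simply rejects the move.
    """
    needed = {"time", "species", "value", "sigma"}
    if not needed <= set(reference.columns):
        raise ValidationError(
            f"reference table needs columns {sorted(needed)}")
    t_max = float(reference["time"].max())
    if t_max > model.horizon:
        raise ValidationError(
            f"reference extends to t={t_max:g} beyond horizon "
            f"{model.horizon:g}")
    try:
        m = model.with_updates(params=dict(params))
        traj = integrate(m, horizon=max(t_max, 1e-6 * model.horizon),
                         rtol=rtol, atol=atol, n_points=1001)
    except SifkitError:
        return float("inf")
    total = 0.0
    for species, grp in reference.groupby("species"):
        try:
            sim = np.interp(grp["time"].to_numpy(), traj.times,
                            traj.value(species))
        except SifkitError:
            return float("inf")
        r = (sim - grp["value"].to_numpy()) / grp["sigma"].to_numpy()
        total += float(np.sum(r * r))
    return total


def make_chisq_energy(model: OdeModel, reference: pd.DataFrame, **kwargs):
    """Close over a model/reference pair as an ``energy(params)`` callable."""
    def energy(params):
        return chisq_energy(model, params, reference, **kwargs)
    return energy


def metropolis_accept(e_old: float, e_new: float, beta: float, rng) -> bool:
    """Accept with probability ``min(1, exp(-beta (e_new - e_old)))``."""
    if beta <= 0:
        raise ValidationError("beta must be positive")
    if e_new <= e_old:
        return True
    if not math.isfinite(e_new):
        return False
    return rng.random() < math.exp(-beta * (e_new - e_old))


def swap_accept(replica_m: ReplicaState, replica_m1: ReplicaState, rng) -> bool:
    """Adjacent-pair exchange with probability ``min(1, exp(dbeta * dE))``."""
    dbeta = replica_m1.beta - replica_m.beta
    de = replica_m1.energy - replica_m.energy
    if not math.isfinite(de):
        # one replica stuck at infinite energy: swap iff it is the one
        # moving to the hotter temperature (exp(arg) with arg = -inf -> 0,
        # +inf -> always)
        arg = dbeta * de
        return bool(arg > 0)
    arg = dbeta * de
    if arg >= 0:
        return True
    return rng.random() < math.exp(arg)


def run_remc(energy: Callable[[Mapping[str, float]], float],
             initial_params: Mapping[str, float],
             free_params: Sequence[str],
             betas: Sequence[float],
             n_iter: int,
             *, swap_interval: int = 10, e_min: int = -4, e_max: int = -1,
             seed: int = 0, record_every: int = 1) -> REMCResult:
    """Run replica-exchange Metropolis sampling of ``energy``.

    One randomly chosen free parameter is perturbed per iteration;
    non-positive proposals are rejected outright (rate constants are
    positive). The run is exactly reproducible for a fixed ``seed``.
    With ``n_iter = 0`` the initial states are returned unchanged.
    """
    betas = tuple(float(b) for b in betas)
    if any(b <= 0 for b in betas) or list(betas) != sorted(betas):
        raise ValidationError("betas must be positive and ascending")
    free = list(free_params)
    if not free:
        raise ValidationError("free_params must not be empty")
    unknown = set(free) - set(initial_params)
    if unknown:
        raise ValidationError(f"free parameters {sorted(unknown)} not in "
                              "initial_params")
    rng = np.random.default_rng(seed)
    e0 = float(energy(initial_params))
    replicas = [dict(initial_params) for _ in betas]
    energies = [e0 for _ in betas]

    best_params, best_energy = dict(initial_params), e0
    traces = [[] for _ in betas]
    accepts = [0 for _ in betas]
    attempts = [0 for _ in betas]
    swap_attempts = 0
    swap_accepts = 0
    all_failed = 0

    for it in range(int(n_iter)):
        for m, beta in enumerate(betas):
            name = free[int(rng.integers(len(free)))]
            step = propose_step(rng, e_min, e_max)
            proposal = dict(replicas[m])
            proposal[name] = proposal[name] + step
            attempts[m] += 1
            if proposal[name] <= 0:
                accepted = False
            else:
                e_new = float(energy(proposal))
                accepted = metropolis_accept(energies[m], e_new, beta, rng)
                if accepted:
                    replicas[m] = proposal
                    energies[m] = e_new
                    if e_new < best_energy:
                        best_params, best_energy = dict(proposal), e_new
            if accepted:
                accepts[m] += 1
            if it % record_every == 0:
                traces[m].append({"iteration": it, "energy": energies[m],
                                  **{k: replicas[m][k] for k in free}})
        if not any(math.isfinite(e) for e in energies):
            all_failed += 1
            if all_failed >= 50:
                raise SifkitError(
                    "all replicas stuck at infinite energy (persistent "
                    "integration failure); check model/reference setup")
        else:
            all_failed = 0
        if swap_interval > 0 and len(betas) > 1 and (it + 1) % swap_interval == 0:
            m = int(rng.integers(len(betas) - 1))
            swap_attempts += 1
            rm = ReplicaState(replicas[m], betas[m], energies[m])
            rm1 = ReplicaState(replicas[m + 1], betas[m + 1], energies[m + 1])
            if swap_accept(rm, rm1, rng):
                swap_accepts += 1
                replicas[m], replicas[m + 1] = replicas[m + 1], replicas[m]
                energies[m], energies[m + 1] = energies[m + 1], energies[m]

    chains = [pd.DataFrame(tr if tr else
                           [{"iteration": -1, "energy": energies[m],
                             **{k: replicas[m][k] for k in free}}])
              for m, tr in enumerate(traces)]
    move_acc = tuple(a / t if t else 0.0 for a, t in zip(accepts, attempts))
    return REMCResult(chains=chains, best_params=best_params,
                      best_energy=best_energy, betas=betas,
                      move_acceptance=move_acc,
                      swap_attempts=swap_attempts, swap_accepts=swap_accepts)
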