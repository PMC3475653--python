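"""Small ODE systems with named per-term perturbation channels.

An :class:`OdeModel` bundles a right-hand-side factory with named
parameters, initial conditions and *channels*: multiplicative factors
attached to individual rate terms. Perturbing a channel scales one term
without touching the parameter symbol it contains, which matters because a
single rate constant (e.g. the cyclin degradation rate ``k_d``) can appear
in several terms that a mutation perturbs with different weights.

Integration is delegated to :func:`scipy.integrate.solve_ivp` with a
stiff-capable method; trajectories are returned on a dense uniform grid so
threshold events can be located by interpolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import IntegrationError, NoCrossingError, ValidationError

__all__ = [
    "OdeModel",
    "Trajectory",
    "ThresholdEvent",
    "PerturbationSpec",
    "integrate",
    "first_crossing",
    "apply_perturbation",
]

#: default integration settings; steep switch dynamics near the G2-M
#: transition need tight tolerances and a dense output grid.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_NPOINTS = 4001


@dataclass(frozen=True)
class PerturbationSpec:
    """A weighted set of channels plus a total relative perturbation size.

    ``components`` maps channel names to weights; the weights must sum to
    one so that ``delta`` is the *total* relative perturbation, split
    across channels as ``1 + weight * delta`` multipliers. ``delta`` may be
    zero, in which case applying the spec is the identity.
    """

    components: tuple
    delta: float = 0.1
    label: str = ""

    def __post_init__(self):
        comps = tuple((str(c), float(w)) for c, w in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValidationError("PerturbationSpec needs at least one component")
        total = sum(w for _, w in comps)
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(
                f"channel weights must sum to 1.0 (got {total!r}) in spec "
                f"{self.label or comps}"
            )
        if self.delta < 0:
            raise ValidationError("delta must be non-negative")

    @property
    def channels(self):
        return tuple(c for c, _ in self.components)

    def multipliers(self):
        """Per-channel multipliers ``1 + w * delta``."""
        return {c: 1.0 + w * self.delta for c, w in self.components}


@dataclass(frozen=True)
class OdeModel:
    """A named ODE system with channelled rate terms.

    ``rhs_factory(params, multipliers)`` must return a callable
    ``f(t, y) -> dy/dt`` over the state vector ordered as ``species``.
    ``channel_multipliers`` all default to 1.0 (the unperturbed system).
    """

    name: str
    species: tuple
    params: Mapping[str, float]
    initial_conditions: Mapping[str, float]
    horizon: float
    channels: tuple
    rhs_factory: Callable = field(repr=False, compare=False)
    channel_multipliers: Mapping[str, float] = field(default=None)
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "initial_conditions", dict(self.initial_conditions))
        mults = dict.fromkeys(self.channels, 1.0)
        if self.channel_multipliers:
            unknown = set(self.channel_multipliers) - set(self.channels)
            if unknown:
                raise ValidationError(
                    f"unknown channels {sorted(unknown)}; valid channels: "
                    f"{sorted(self.channels)}"
                )
            mults.update(self.channel_multipliers)
        object.__setattr__(self, "channel_multipliers", mults)
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel names must be unique")
        missing = set(self.species) - set(self.initial_conditions)
        if missing:
            raise ValidationError(f"initial conditions missing for {sorted(missing)}")
        if self.horizon <= 0:
            raise ValidationError("horizon must be positive")

    # -- functional updates -------------------------------------------------
    def with_updates(self, params=None, initial_conditions=None,
                     multipliers=None, horizon=None):
        """Return a copy with selected fields replaced."""
        new_params = dict(self.params)
        if params:
            unknown = set(params) - set(self.params)
            if unknown:
                raise ValidationError(
                    f"unknown parameters {sorted(unknown)}; valid: "
                    f"{sorted(self.params)}"
                )
            new_params.update(params)
        new_ics = dict(self.initial_conditions)
        if initial_conditions:
            unknown = set(initial_conditions) - set(self.species)
            if unknown:
                raise ValidationError(f"unknown species {sorted(unknown)}")
            new_ics.update(initial_conditions)
        new_mults = dict(self.channel_multipliers)
        if multipliers:
            unknown = set(multipliers) - set(self.channels)
            if unknown:
                raise ValidationError(
                    f"unknown channels {sorted(unknown)}; valid channels: "
                    f"{sorted(self.channels)}"
                )
            for ch, m in multipliers.items():
                new_mults[ch] = float(m)
        return dataclasses.replace(
            self, params=new_params, initial_conditions=new_ics,
            channel_multipliers=new_mults,
            horizon=self.horizon if horizon is None else float(horizon))

    def rhs(self):
        return self.rhs_factory(self.params, dict(self.channel_multipliers))

    def y0(self):
        return np.array([self.initial_conditions[s] for s in self.species], float)

    def to_config(self):
        """Plain-dict description (species, params, ICs, horizon)."""
        return {
            "family": self.name,
            "species": list(self.species),
            "params": {k: float(v) for k, v in self.params.items()},
            "initial_conditions": {k: float(v)
                                   for k, v in self.initial_conditions.items()},
            "horizon": float(self.horizon),
        }


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus state values for all species of one model run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_species, n_times)
    species: tuple
    model_ref: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        y = np.asarray(self.states, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        object.__setattr__(self, "species", tuple(self.species))
        if y.shape != (len(self.species), t.size):
            raise ValidationError(
                f"states shape {y.shape} does not match "
                f"({len(self.species)}, {t.size})")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValidationError("trajectory contains non-finite values")

    def value(self, species):
        try:
            i = self.species.index(species)
        except ValueError:
            raise ValidationError(
                f"species {species!r} not in trajectory {self.species}") from None
        return self.states[i]

    def at(self, t):
        """All species interpolated (PCHIP) at time ``t``."""
        return {s: float(PchipInterpolator(self.times, self.value(s))(t))
                for s in self.species}

    def to_frame(self):
        df = pd.DataFrame({"time": self.times})
        for s in self.species:
            df[s] = self.value(s)
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_ref=""):
        df = pd.read_csv(path)
        if df.columns[0] != "time":
            raise ValidationError("trajectory CSV must start with a 'time' column")
        species = tuple(df.columns[1:])
        return cls(times=df["time"].to_numpy(),
                   states=df[list(species)].to_numpy().T,
                   species=species, model_ref=model_ref)


@dataclass(frozen=True)
class ThresholdEvent:
    """An upward threshold crossing located by interpolation."""

    species: str
    level: float
    time: float
    state_at_crossing: Mapping[str, float]


def integrate(model: OdeModel, overrides=None, horizon=None, *,
              rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
              n_points=DEFAULT_NPOINTS, method="LSODA") -> Trajectory:
    """Integrate ``model`` and return a dense :class:`Trajectory`.

    ``overrides`` may mix parameter values, channel multipliers and
    ``init:<species>`` initial-condition values; keys are routed by name.
    A non-finite state aborts with :class:`IntegrationError` naming the
    first offending species and time.
    """
    m = model
    if overrides:
        params, mults, ics = {}, {}, {}
        for k, v in overrides.items():
            if k.startswith("init:"):
                ics[k[5:]] = v
            elif k in m.params:
                params[k] = v
            elif k in m.channels:
                mults[k] = v
            else:
                raise ValidationError(
                    f"override {k!r} is neither a parameter, channel nor "
                    f"'init:<species>' of model {m.name!r}")
        m = m.with_updates(params=params, initial_conditions=ics,
                           multipliers=mults)
    T = float(m.horizon if horizon is None else horizon)
    if T <= 0:
        raise ValidationError("horizon must be positive")
    t_eval = np.linspace(0.0, T, int(n_points))
    f = m.rhs()

    class _Diverged(Exception):
        pass

    def guarded(t, y):
        ya = np.asarray(y)
        if not np.all(np.isfinite(ya)) or np.any(np.abs(ya) > 1e30):
            # abort immediately: stiff steppers can otherwise grind at a
            # finite-time singularity almost indefinitely
            bad = np.nonzero(~np.isfinite(ya))[0]
            i = int(bad[0]) if bad.size else int(np.argmax(np.abs(ya)))
            raise _Diverged((m.species[i], float(t)))
        return f(t, y)

    try:
        sol = solve_ivp(guarded, (0.0, T), m.y0(), method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval)
    except _Diverged as exc:
        species, t_bad = exc.args[0]
        raise IntegrationError(
            f"integration of {m.name!r} produced non-finite or divergent "
            f"{species!r} near t={t_bad:g}",
            species=species, time=t_bad) from None
    if not sol.success or sol.t.size < t_eval.size:
        # locate the first bad point for the error message
        y = sol.y if sol.y.size else np.full((len(m.species), 1), np.nan)
        bad = ~np.isfinite(y)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise IntegrationError(
                f"integration of {m.name!r} produced non-finite "
                f"{m.species[i]!r} near t={sol.t[min(j, sol.t.size - 1)]:g}",
                species=m.species[i],
                time=float(sol.t[min(j, sol.t.size - 1)]))
        raise IntegrationError(
            f"integration of {m.name!r} failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        i, j = np.argwhere(~np.isfinite(sol.y))[0]
        raise IntegrationError(
            f"integration of {m.name!r} produced non-finite "
            f"{m.species[i]!r} at t={sol.t[j]:g}",
            species=m.species[i], time=float(sol.t[j]))
    return Trajectory(times=sol.t, states=sol.y, species=m.species,
                      model_ref=m.name)


def first_crossing(traj: Trajectory, species: str, level: float) -> ThresholdEvent:
    """Earliest upward crossing of ``level`` by ``species``.

    The crossing time is refined with a monotone cubic (PCHIP)
    interpolant and a bracketed root solve, so it is accurate well beyond
    the output grid spacing; the full state is interpolated at the same
    time.
    """
    s = traj.value(species)
    t = traj.times
    if s[0] >= level:
        # already at/above the level: treat t=0 as the crossing only if
        # exactly at the level; "above from the start" is not an upward
        # crossing of interest here.
        below = s < level
        if not below.any():
            raise NoCrossingError(
                f"{species} starts at {s[0]:g} >= level {level:g} and never "
                "crosses upward")
    idx = np.nonzero((s[:-1] < level) & (s[1:] >= level))[0]
    if idx.size == 0:
        raise NoCrossingError(
            f"{species} never reaches {level:g} within horizon "
            f"[{t[0]:g}, {t[-1]:g}] (max {s.max():g})")
    j = int(idx[0])
    interp = PchipInterpolator(t, s)
    if s[j + 1] == level:
        tc = float(t[j + 1])
    else:
        tc = float(brentq(lambda x: interp(x) - level, t[j], t[j + 1],
                          xtol=1e-12, rtol=1e-14))
    return ThresholdEvent(species=species, level=float(level), time=tc,
                          state_at_crossing=traj.at(tc))


def apply_perturbation(model: OdeModel, spec: PerturbationSpec) -> OdeModel:
    """Return a copy of ``model`` with channel multipliers scaled.

    Each component channel's multiplier is scaled by ``1 + weight*delta``;
    the original model is left untouched. Unknown channels raise with the
    list of valid ones.
    """
    unknown = set(spec.channels) - set(model.channels)
    if unknown:
        raise ValidationError(
            f"spec {spec.label!r} references unknown channels "
            f"{sorted(unknown)}; valid channels: {sorted(model.channels)}")
    mults = {ch: model.channel_multipliers[ch] * m
             for ch, m in spec.multipliers().items()}
    return model.with_updates(multipliers=mults)
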