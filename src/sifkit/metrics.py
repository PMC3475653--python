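"""Scalar readouts of pathway trajectories.

Two families of readout are used throughout the package:

* G2-M: the concentration of total cyclin B at the moment active MPF
  first reaches 2.0 (mitotic entry). Because the cell grows linearly in
  time during interphase, cyclin at entry is a proxy for cell length at
  septation.
* MAPK: three features of the active-Erk pulse — amplitude (maximum
  activation), peak time (earliest time of maximum) and duration (time
  from stimulation until the signal has fallen to 50% of its maximum,
  measured on the falling edge after the peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoCrossingError
from .model import OdeModel, Trajectory, first_crossing, integrate

__all__ = ["CurveMetrics", "CurveDeviation", "mapk_metrics", "g2m_readout",
           "curve_deviation", "MITOTIC_ENTRY_LEVEL"]

#: active-MPF level defining mitotic entry (dimensionless)
MITOTIC_ENTRY_LEVEL = 2.0


@dataclass(frozen=True)
class CurveMetrics:
    """Amplitude / peak-time / duration summary of one reporter series.

    ``censored`` is set when the series never falls to half its maximum
    within the horizon; ``duration`` then equals the horizon end.
    """

    amplitude: float
    peak_time: float
    duration: float
    censored: bool = False

    def as_dict(self):
        return {"amplitude": self.amplitude, "peak_time": self.peak_time,
                "duration": self.duration, "censored": self.censored}


@dataclass(frozen=True)
class CurveDeviation:
    """Per-metric differences (mutant minus wild type)."""

    d_amplitude: float
    d_peak_time: float
    d_duration: float
    censored: bool = False


def _refine_peak(t, s, i):
    """Quadratic refinement of a discrete maximum (keeps metrics stable
    under re-gridding); falls back to the grid point at the boundaries."""
    if i == 0 or i == len(s) - 1:
        return float(t[i]), float(s[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = s[i - 1], s[i], s[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if denom >= 0:  # flat or non-concave: keep the grid point
        return float(t1), float(y1)
    h = t1 - t0
    shift = 0.5 * h * (y0 - y2) / denom
    shift = float(np.clip(shift, -h, h))
    tp = t1 + shift
    yp = y1 - 0.25 * (y0 - y2) * shift / h
    return float(tp), float(max(yp, y1))


def mapk_metrics(traj: Trajectory, reporter: str = "Erk*") -> CurveMetrics:
    """Amplitude, peak time and duration of a reporter pulse.

    Ties in the maximum resolve to the earliest attaining time; the
    half-maximum crossing is located by linear interpolation between the
    bracketing grid points of the falling edge after the peak.
    """
    s = traj.value(reporter)
    t = traj.times
    i = int(np.argmax(s))  # earliest index attaining the maximum
    peak_time, amplitude = _refine_peak(t, s, i)
    if amplitude <= 0:
        # flat-at-zero series: no pulse at all
        return CurveMetrics(amplitude=float(s[i]), peak_time=float(t[i]),
                            duration=float(t[-1]), censored=True)
    half = 0.5 * amplitude
    after = np.nonzero((t >= peak_time) & (s <= half))[0]
    after = after[after > 0]
    if after.size == 0:
        return CurveMetrics(amplitude=amplitude, peak_time=peak_time,
                            duration=float(t[-1]), censored=True)
    j = int(after[0])
    t0, t1 = t[j - 1], t[j]
    s0, s1 = s[j - 1], s[j]
    duration = float(t0 + (half - s0) * (t1 - t0) / (s1 - s0))
    return CurveMetrics(amplitude=amplitude, peak_time=peak_time,
                        duration=duration, censored=False)


def g2m_readout(model: OdeModel, overrides=None, *, level=MITOTIC_ENTRY_LEVEL,
                **integrate_kwargs) -> float:
    """Total cyclin B at the first upward crossing of active MPF = ``level``.

    Propagates :class:`~sifkit.errors.NoCrossingError` unchanged when the
    perturbed system never enters mitosis within the horizon.
    """
    traj = integrate(model, overrides=overrides, **integrate_kwargs)
    event = first_crossing(traj, "MPF", level)
    return float(event.state_at_crossing["CycB"])


def curve_deviation(traj_mutant: Trajectory, traj_wildtype: Trajectory,
                    reporter: str = "Erk*") -> CurveDeviation:
    """Metric differences mutant - wild type for a shared reporter."""
    mm = mapk_metrics(traj_mutant, reporter)
    mw = mapk_metrics(traj_wildtype, reporter)
    return CurveDeviation(
        d_amplitude=mm.amplitude - mw.amplitude,
        d_peak_time=mm.peak_time - mw.peak_time,
        d_duration=mm.duration - mw.duration,
        censored=mm.censored or mw.censored,
    )
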