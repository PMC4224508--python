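"""Electrophysiological measurements on traces and activation maps.

Conventions (documented once, used everywhere): activation is an upward
crossing of the activation threshold (default u = 0.5), with linear
interpolation between samples; APD90 runs from activation onset to 90%
return from the peak toward the pre-upstroke baseline; the refractory
period is the shortest S1-S2 coupling interval (stimulus onset to stimulus
onset) for which the premature wave still reaches the far probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "APTrace",
    "ActivationMap",
    "PropagationFailure",
    "MeasurementError",
    "activation_times",
    "conduction_velocity",
    "apd90",
    "max_upstroke",
    "rp_scan",
    "cycle_length",
    "dominant_frequency",
    "conduction_ratio",
]


class MeasurementError(ValueError):
    """Raised when a trace does not contain the feature being measured."""


class PropagationFailure(Exception):
    """Signals that a wave failed to reach the measurement site."""


@dataclass
class APTrace:
    """Sampled excitation (or membrane potential) at one probe site."""

    name: str
    t: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.u.shape:
            raise MeasurementError("trace arrays must be congruent 1-D")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise MeasurementError("trace time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class ActivationMap:
    """Per-voxel first-crossing time of the activation threshold (ms).

    Unactivated voxels are NaN.
    """

    times: np.ndarray
    threshold: float
    dx_um: float


def activation_times(trace: APTrace, threshold: float = 0.5,
                     t_from: float = 0.0) -> np.ndarray:
    """All upward threshold-crossing times (linearly interpolated)."""
    u, t = trace.u, trace.t
    idx = np.where((u[:-1] < threshold) & (u[1:] >= threshold))[0]
    if len(idx) == 0:
        return np.empty(0)
    frac = (threshold - u[idx]) / (u[idx + 1] - u[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    return times[times >= t_from]


def conduction_velocity(amap: ActivationMap, from_layer: int = 10,
                        to_layer: int = 40, axis: int = 0) -> float:
    """Mean conduction velocity between two element layers, in m/s.

    Layers are 1-based along ``axis`` (layer 10 = index 9).  The velocity is
    (distance between layer centroids) / (mean activation-time difference).
    Raises PropagationFailure if either layer is (partly) unactivated and
    MeasurementError on a zero time difference.
    """
    times = np.moveaxis(amap.times, axis, 0)
    t_a = times[from_layer - 1]
    t_b = times[to_layer - 1]
    if np.any(np.isnan(t_a)) or np.any(np.isnan(t_b)):
        raise PropagationFailure(
            f"layer {from_layer if np.any(np.isnan(t_a)) else to_layer} "
            "not fully activated"
        )
    dt_ms = float(np.nanmean(t_b) - np.nanmean(t_a))
    if dt_ms == 0:
        raise MeasurementError("zero activation-time difference")
    dist_mm = abs(to_layer - from_layer) * amap.dx_um / 1000.0
    return dist_mm / dt_ms  # mm/ms == m/s


def _onset_index(trace: APTrace, threshold: float):
    cross = np.where((trace.u[:-1] < threshold)
                     & (trace.u[1:] >= threshold))[0]
    if len(cross) == 0:
        raise MeasurementError("trace contains no activation")
    return int(cross[0])


def apd90(trace: APTrace, threshold: float = 0.5,
          repol_fraction: float = 0.9, baseline_window_ms: float = 5.0
          ) -> float:
    """Action potential duration at 90% repolarization (ms).

    Onset = first upward threshold crossing; baseline = minimum of the
    trace over the window immediately before onset; the repolarization
    level is peak - repol_fraction * (peak - baseline), located with linear
    interpolation.
    """
    i_on = _onset_index(trace, threshold)
    dt = trace.dt
    w = max(1, int(round(baseline_window_ms / dt)))
    base = float(trace.u[max(0, i_on - w):i_on + 1].min()) if i_on > 0 \
        else float(trace.u[0])
    seg = trace.u[i_on:]
    i_pk = int(np.argmax(seg))
    peak = float(seg[i_pk])
    if peak <= threshold:
        raise MeasurementError("no full action potential after onset")
    level = peak - repol_fraction * (peak - base)
    after = seg[i_pk:]
    below = np.where(after <= level)[0]
    if len(below) == 0:
        raise MeasurementError("trace does not repolarize to 90%")
    j = below[0]
    if j == 0:
        t_cross = trace.t[i_on + i_pk]
    else:
        u1, u2 = after[j - 1], after[j]
        f = (u1 - level) / (u1 - u2)
        t1 = trace.t[i_on + i_pk + j - 1]
        t2 = trace.t[i_on + i_pk + j]
        t_cross = t1 + f * (t2 - t1)
    t_on = activation_times(trace, threshold)[0]
    return float(t_cross - t_on)


def max_upstroke(trace: APTrace, apa_mv: float | None = None):
    """Maximum upstroke velocity: max du/dt in 1/ms.

    With ``apa_mv`` (action-potential amplitude in mV) also returns the
    dimensional value in mV/ms as a second element.
    """
    if len(trace.u) < 2:
        raise MeasurementError("trace too short")
    dudt = np.diff(trace.u) / np.diff(trace.t)
    m = float(np.max(dudt))
    if apa_mv is None:
        return m
    return m, m * apa_mv


def rp_scan(propagates, lo: float, hi: float, resolution: float = 1.0
            ) -> float:
    """Shortest coupling interval with a propagated response.

    ``propagates(ci)`` must be monotone (False below the refractory period,
    True above).  Bisection to the given resolution; raises
    PropagationFailure if even ``hi`` fails.
    """
    if not propagates(hi):
        raise PropagationFailure(
            f"S2 does not propagate even at coupling interval {hi} ms"
        )
    lo_f, hi_f = float(lo), float(hi)
    if propagates(lo_f):
        return lo_f
    while hi_f - lo_f > resolution:
        mid = round((lo_f + hi_f) / 2.0 / resolution) * resolution
        if mid <= lo_f or mid >= hi_f:
            break
        if propagates(mid):
            hi_f = mid
        else:
            lo_f = mid
    return hi_f


def cycle_length(trace: APTrace, threshold: float = 0.5,
                 discard_first: int = 1) -> float:
    """Mean interval between successive spontaneous activations (ms)."""
    times = activation_times(trace, threshold)
    if len(times) < discard_first + 3:
        raise MeasurementError(
            f"need at least {discard_first + 3} activations, "
            f"got {len(times)}"
        )
    return float(np.mean(np.diff(times[discard_first:])))


def dominant_frequency(trace: APTrace, threshold: float = 0.5,
                       window: tuple | None = None) -> float:
    """Activation rate (Hz) from event counting over the window."""
    times = activation_times(trace, threshold)
    t0 = window[0] if window else trace.t[0]
    t1 = window[1] if window else trace.t[-1]
    n = int(np.sum((times >= t0) & (times <= t1)))
    span_s = (t1 - t0) / 1000.0
    if span_s <= 0:
        raise MeasurementError("empty analysis window")
    return n / span_s


@dataclass
class ConductionRatio:
    """n:m activation-count ratio between an upstream and downstream site."""

    n: int
    m: int
    per_beat: list          # downstream-interval ratios (beats skipped + 1)

    @property
    def mixed(self) -> bool:
        return len(set(self.per_beat)) > 1

    def __str__(self):
        s = f"{self.n}:{self.m}"
        if self.mixed:
            s += " (mixed: " + "/".join(
                f"{r}:1" for r in sorted(set(self.per_beat))) + ")"
        return s


def conduction_ratio(upstream: APTrace, downstream: APTrace,
                     window: tuple | None = None,
                     threshold: float = 0.5) -> ConductionRatio:
    """Reduced integer activation-count ratio upstream:downstream.

    Also reports the per-beat pattern (how many upstream beats pass between
    successive downstream activations), so alternating block patterns such
    as 2:1 / 3:1 are visible.
    """
    tu = activation_times(upstream, threshold)
    td = activation_times(downstream, threshold)
    if window is not None:
        tu = tu[(tu >= window[0]) & (tu <= window[1])]
        td = td[(td >= window[0]) & (td <= window[1])]
    if len(tu) < 3:
        raise MeasurementError("need at least 3 upstream activations")
    if len(td) == 0:
        return ConductionRatio(len(tu), 0, [])
    frac = Fraction(len(tu), len(td))
    per_beat = []
    for a, b in zip(td[:-1], td[1:]):
        per_beat.append(int(np.sum((tu > a) & (tu <= b))))
    return ConductionRatio(frac.numerator, frac.denominator, per_beat)
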