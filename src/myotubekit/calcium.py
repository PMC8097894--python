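"""Ca²⁺ transient parametrization under electric-field burst stimulation.

Myotubes loaded with a cytosolic Ca²⁺ dye are stimulated with repeated
bursts (default: 1 s at 10 Hz, every 10 s, for 3 min) while fluorescence
is sampled at ~3.3 Hz.  This module normalizes each recording to its
pre-stimulus baseline (F/F0), extracts one peak amplitude per burst,
classifies responders (first amplitude > 0.5 ΔF/F0), measures the decay
time of the first transient (1/e crossing by default, monoexponential
tau as an alternative) and the percentage of remaining Ca²⁺ (last
amplitude / first amplitude × 100).

Time axis convention: t = 0 s is the onset of the first burst; the
pre-stimulus baseline lives at negative times.  Burst onsets are taken
from the protocol (stimulus-locked analysis), not detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

#: ΔF/F0 classification threshold separating responders from non-responders.
RESPONDER_THRESHOLD = 0.5
#: Extra seconds after burst end searched for the (decay-delayed) maximum.
PEAK_SEARCH_EXTRA = 2.0
#: Default baseline window, seconds relative to first burst onset.
BASELINE_WINDOW = (-5.0, 0.0)


class TraceError(ValueError):
    """Raised for traces inconsistent with the stimulation protocol."""


@dataclass(frozen=True)
class StimulationProtocol:
    """Electric-field burst stimulation protocol.

    Defaults are repetitive bursts of 1 s at 10 Hz every 10 s for 3 min,
    each pulse lasting 2 ms (metadata only; pulses are not resolved at
    the ~3.3 Hz acquisition rate).
    """

    burst_duration: float = 1.0  # s
    intra_burst_rate: float = 10.0  # Hz
    pulse_width_ms: float = 2.0  # metadata only
    inter_burst_period: float = 10.0  # s
    total_duration: float = 180.0  # s

    def __post_init__(self) -> None:
        if not (self.burst_duration < self.inter_burst_period):
            raise ValueError("burst_duration must be < inter_burst_period")
        if not (self.total_duration >= self.inter_burst_period):
            raise ValueError("total_duration must be ≥ inter_burst_period")
        if self.total_duration < self.burst_duration:
            raise ValueError("protocol shorter than one burst")

    @property
    def burst_onsets(self) -> np.ndarray:
        """Burst onset times in seconds; t = 0 is the first onset."""
        onsets = np.arange(0.0, self.total_duration, self.inter_burst_period)
        return onsets[onsets + self.burst_duration <= self.total_duration]

    @property
    def n_bursts(self) -> int:
        return len(self.burst_onsets)


@dataclass
class FluorescenceTrace:
    """A calibrated F/F0 time series."""

    time: np.ndarray  # s, monotone increasing
    F: np.ndarray  # raw intensity, a.u.
    F0: float  # baseline, a.u.
    normalized: np.ndarray  # F / F0

    @property
    def dt(self) -> float:
        """Median sampling interval, s."""
        return float(np.median(np.diff(self.time)))


@dataclass
class DecayResult:
    time_s: float  # NaN when censored
    censored: bool
    method: str  # "1/e crossing" or "exp fit"


@dataclass
class TransientMetrics:
    """Per-cell parametrization of one burst-stimulation recording."""

    per_burst_amplitude: np.ndarray  # ΔF/F0, one per burst
    first_amplitude: float
    is_responder: bool
    decay_time: float  # s (1/e crossing); NaN when censored
    decay_censored: bool
    remaining_pct: float  # 100 × last/first amplitude
    decay_tau_fit: float | None = None  # monoexponential tau, s


# ----------------------------------------------------------------------

def normalize_trace(
    time: np.ndarray,
    F: np.ndarray,
    protocol: StimulationProtocol | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> FluorescenceTrace:
    """Express a raw trace as F/F0.

    F0 is the mean raw fluorescence over ``baseline_window`` (seconds,
    half-open [start, stop)), which must precede the first burst onset
    (t = 0 when a protocol is given) and contain at least 3 samples.
    """
    time = np.asarray(time, dtype=float)
    F = np.asarray(F, dtype=float)
    if time.ndim != 1 or time.shape != F.shape:
        raise TraceError("time and F must be 1-D arrays of equal length")
    if np.any(np.diff(time) <= 0):
        raise TraceError("time must be strictly increasing")
    start, stop = baseline_window
    if protocol is not None and stop > 0:
        raise TraceError("baseline window overlaps stimulation (t ≥ 0)")
    sel = (time >= start) & (time < stop)
    if sel.sum() < 3:
        raise TraceError("baseline window must contain ≥ 3 samples")
    F0 = float(F[sel].mean())
    if F0 <= 0:
        raise TraceError(f"baseline F0 must be > 0, got {F0}")
    return FluorescenceTrace(time=time, F=F, F0=F0, normalized=F / F0)


def per_burst_peaks(
    trace: FluorescenceTrace,
    protocol: StimulationProtocol,
    search_extra: float = PEAK_SEARCH_EXTRA,
) -> np.ndarray:
    """One ΔF/F0 peak amplitude per burst.

    For burst k with onset t_k, the amplitude is
    ``max(F/F0 over [t_k, t_k + burst_duration + search_extra]) − 1``,
    clipped at 0.  Raises listing the missing bursts if the trace does
    not cover the protocol.
    """
    onsets = protocol.burst_onsets
    t_end = trace.time[-1]
    missing = [k for k, t0 in enumerate(onsets) if t0 > t_end + 1e-9]
    if missing:
        raise TraceError(
            f"trace ends at {t_end:.2f} s; missing bursts {missing} "
            f"(onsets {onsets[missing[0]]:.1f} s onward)"
        )
    window = protocol.burst_duration + search_extra
    amps = np.empty(len(onsets))
    for k, t0 in enumerate(onsets):
        sel = (trace.time >= t0 - 1e-9) & (trace.time <= t0 + window + 1e-9)
        if not sel.any():
            raise TraceError(f"no samples in peak window of burst {k}")
        amps[k] = trace.normalized[sel].max() - 1.0
    return np.clip(amps, 0.0, None)


def classify_responder(
    first_amplitude: float, threshold: float = RESPONDER_THRESHOLD
) -> bool:
    """Responder iff the first transient amplitude strictly exceeds the
    threshold (ΔF/F0, default 0.5); an exact tie is a non-responder."""
    return first_amplitude > threshold


def decay_time(
    trace: FluorescenceTrace,
    protocol: StimulationProtocol,
    first_amplitude: float | None = None,
) -> DecayResult:
    """Decay time of the first transient: time from the first-burst peak
    to the first crossing of baseline + amplitude/e, with linear
    interpolation between samples.

    If the trace never crosses that level before the second burst onset
    the value is censored (NaN, ``censored=True``).
    """
    onsets = protocol.burst_onsets
    t0 = onsets[0]
    t_next = onsets[1] if len(onsets) > 1 else trace.time[-1] + trace.dt
    window = protocol.burst_duration + PEAK_SEARCH_EXTRA
    sel = (trace.time >= t0 - 1e-9) & (trace.time <= t0 + window + 1e-9)
    if not sel.any():
        raise TraceError("no samples in the first-burst peak window")
    seg = np.flatnonzero(sel)
    i_peak = seg[np.argmax(trace.normalized[seg])]
    peak_t = trace.time[i_peak]
    if first_amplitude is None:
        first_amplitude = float(trace.normalized[i_peak] - 1.0)
    if first_amplitude <= 0:
        raise TraceError("decay time requires first_amplitude > 0")
    target = 1.0 + first_amplitude / math.e
    after = np.flatnonzero((trace.time >= peak_t) & (trace.time < t_next - 1e-9))
    y = trace.normalized
    for j0, j1 in zip(after[:-1], after[1:]):
        if y[j0] > target >= y[j1]:
            frac = (y[j0] - target) / (y[j0] - y[j1])
            t_cross = trace.time[j0] + frac * (trace.time[j1] - trace.time[j0])
            return DecayResult(float(t_cross - peak_t), False, "1/e crossing")
    return DecayResult(float("nan"), True, "1/e crossing")


def fit_decay_tau(
    trace: FluorescenceTrace,
    protocol: StimulationProtocol,
) -> float:
    """Monoexponential time constant of the first transient's decay.

    Fits ``1 + A·exp(−(t − t_peak)/tau)`` to the samples between the
    first-burst peak and the second burst onset.
    """
    onsets = protocol.burst_onsets
    t_next = onsets[1] if len(onsets) > 1 else trace.time[-1] + trace.dt
    window = protocol.burst_duration + PEAK_SEARCH_EXTRA
    sel = (trace.time >= onsets[0] - 1e-9) & (trace.time <= onsets[0] + window + 1e-9)
    seg = np.flatnonzero(sel)
    i_peak = seg[np.argmax(trace.normalized[seg])]
    fit_idx = np.flatnonzero(
        (trace.time >= trace.time[i_peak]) & (trace.time < t_next - 1e-9)
    )
    if len(fit_idx) < 3:
        raise TraceError("too few samples to fit a decay")
    t = trace.time[fit_idx] - trace.time[i_peak]
    y = trace.normalized[fit_idx]
    A0 = max(y[0] - 1.0, 1e-6)

    def model(t, A, tau):
        return 1.0 + A * np.exp(-t / tau)

    popt, _ = curve_fit(
        model, t, y, p0=(A0, 1.0), bounds=([0, 1e-3], [np.inf, np.inf]), maxfev=10000
    )
    return float(popt[1])


def remaining_calcium(per_burst_amplitude: np.ndarray) -> float:
    """Percentage of remaining Ca²⁺: 100 × last/first burst amplitude."""
    amps = np.asarray(per_burst_amplitude, dtype=float)
    if len(amps) == 0:
        raise TraceError("no burst amplitudes")
    if amps[0] <= 0:
        raise TraceError("remaining Ca²⁺ undefined: first amplitude is 0")
    return 100.0 * float(amps[-1] / amps[0])


def analyze_trace(
    trace: FluorescenceTrace,
    protocol: StimulationProtocol,
    threshold: float = RESPONDER_THRESHOLD,
    fit_tau: bool = False,
) -> TransientMetrics:
    """Full per-cell parametrization of one recording."""
    amps = per_burst_peaks(trace, protocol)
    first = float(amps[0])
    responder = classify_responder(first, threshold)
    if first > 0:
        dec = decay_time(trace, protocol, first)
        rem = remaining_calcium(amps)
    else:
        dec = DecayResult(float("nan"), True, "1/e crossing")
        rem = float("nan")
    tau = None
    if fit_tau and first > 0:
        tau = fit_decay_tau(trace, protocol)
    return TransientMetrics(
        per_burst_amplitude=amps,
        first_amplitude=first,
        is_responder=responder,
        decay_time=dec.time_s,
        decay_censored=dec.censored,
        remaining_pct=rem,
        decay_tau_fit=tau,
    )


def population_response_rates(
    metrics: Sequence[TransientMetrics],
    groups: Sequence[str],
) -> dict[str, float]:
    """Fraction of responders per group label."""
    if len(metrics) != len(groups):
        raise ValueError("one group label per cell required")
    out: dict[str, float] = {}
    for g in dict.fromkeys(groups):
        flags = [m.is_responder for m, gi in zip(metrics, groups) if gi == g]
        if not flags:
            raise ValueError(f"empty group {g!r}")
        out[g] = sum(flags) / len(flags)
    return out
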