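"""Scotopic flash ERG feature extraction.

The measurement conventions implemented here:

* repeated trials at one flash luminance are averaged pointwise;
* the baseline is the mean voltage over the pretrial window (time < 0);
* the **a-wave** amplitude is measured from baseline to the most negative
  point of the *unfiltered* averaged trace, its implicit time being the
  latency of that trough from stimulus onset;
* **oscillatory potentials (OPs)** are isolated with a zero-phase
  (forward–backward) digital Butterworth high-pass filter, 25 Hz cutoff by
  default — forward–backward filtering is used so OP implicit times carry
  no phase lag;
* the **b-wave** amplitude is measured from the a-wave trough to the highest
  positive point of the OP-subtracted trace;
* OP1–OP4 implicit times/amplitudes are the first four positive peaks of the
  isolated OP trace inside the search window.

The a-wave is deliberately measured on the raw average while the b-wave is
measured after OP subtraction; this asymmetry is part of the measurement
definition, not an accident.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import io as eio


class GridMismatchError(ValueError):
    """Traces do not share one common time grid."""


class WindowError(ValueError):
    """A measurement window contains no samples."""


class EyeSelectionError(ValueError):
    """Neither eye offers a b-wave at the comparison luminance."""


@dataclass(frozen=True)
class FilterSpec:
    """Digital high-pass filter used to isolate oscillatory potentials.

    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``), squaring the magnitude response and cancelling phase,
    so passband peak times are preserved.
    """

    family: str = "butterworth"
    mode: str = "highpass"
    cutoff_hz: float = 25.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.family != "butterworth" or self.mode != "highpass":
            raise ValueError("only Butterworth high-pass filters are supported")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class Windows:
    """Measurement windows and thresholds (ms / µV).

    ``pre_window_ms=None`` uses the entire pretrial record for the baseline.
    ``edge_trim_ms`` excludes filter edge transients from peak searches.
    ``a_min_amp_uV`` is the detectability floor below which the a-trough
    falls back to (stimulus onset, baseline) as the b-wave reference.
    """

    pre_window_ms: tuple[float, float] | None = None
    a_search_ms: tuple[float, float] = (3.0, 50.0)
    b_search_end_ms: float = 150.0
    op_window_pad_ms: float = 20.0
    min_prominence_uV: float = 5.0
    op_min_spacing_ms: float = 6.0
    edge_trim_ms: float = 10.0
    a_min_amp_uV: float = 10.0


@dataclass
class Trace:
    """A voltage trace on a uniform time grid (ms relative to stimulus onset)."""

    time_ms: np.ndarray
    voltage_uV: np.ndarray

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, float)
        self.voltage_uV = np.asarray(self.voltage_uV, float)
        if self.time_ms.shape != self.voltage_uV.shape:
            raise GridMismatchError("time and voltage lengths differ")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt_ms


@dataclass
class AveragedTrace(Trace):
    n_trials: int = 1
    luminance_log: float = float("nan")
    eye: str = ""
    animal_id: str = ""


def _same_grid(a: np.ndarray, b: np.ndarray, tol: float = 1e-9) -> bool:
    return a.shape == b.shape and bool(np.all(np.abs(a - b) <= tol))


def average_sweeps(sweeps: list[Trace], **meta) -> AveragedTrace:
    """Pointwise arithmetic mean of repeated trials on a common grid."""
    if not sweeps:
        raise ValueError("need at least one sweep")
    grid = sweeps[0].time_ms
    for s in sweeps[1:]:
        if not _same_grid(grid, s.time_ms):
            raise GridMismatchError("sweeps are not on a common time grid")
    mean = np.mean([s.voltage_uV for s in sweeps], axis=0)
    return AveragedTrace(grid.copy(), mean, n_trials=len(sweeps), **meta)


def estimate_baseline(trace: Trace, pre_window_ms: tuple[float, float] | None = None) -> float:
    """Mean voltage over the pretrial window (default: all samples with t < 0)."""
    if pre_window_ms is None:
        mask = trace.time_ms < 0
    else:
        lo, hi = pre_window_ms
        mask = (trace.time_ms >= lo) & (trace.time_ms < min(hi, 0.0))
    if mask.sum() < 1:
        raise WindowError("empty pretrial window")
    return float(trace.voltage_uV[mask].mean())


@functools.lru_cache(maxsize=32)
def _design_sos(order: int, cutoff_hz: float, fs_hz: float):
    return sps.butter(order, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")


def isolate_ops(trace: Trace, filt: FilterSpec = FilterSpec()) -> Trace:
    """High-pass the trace to isolate the oscillatory potentials.

    Zero-phase mode filters forward and backward with odd-reflection
    padding of length >= 3 filter time constants, so passband components
    keep their peak times.
    """
    nyquist = trace.fs_hz / 2.0
    if filt.cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {filt.cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    sos = _design_sos(filt.order, filt.cutoff_hz, round(trace.fs_hz, 9))
    n = len(trace.voltage_uV)
    if filt.zero_phase:
        padlen = min(n - 1, int(3 * trace.fs_hz / filt.cutoff_hz))
        out = sps.sosfiltfilt(sos, trace.voltage_uV, padlen=padlen)
    else:
        out = sps.sosfilt(sos, trace.voltage_uV)
    return Trace(trace.time_ms.copy(), out)


def subtract_ops(trace: Trace, op_trace: Trace) -> Trace:
    """Pointwise difference; ``subtract_ops(t, op) + op`` reconstructs ``t``."""
    if not _same_grid(trace.time_ms, op_trace.time_ms):
        raise GridMismatchError("trace and OP trace are on different grids")
    return Trace(trace.time_ms.copy(), trace.voltage_uV - op_trace.voltage_uV)


def measure_a_wave(
    trace: Trace, baseline_uV: float, search_window_ms: tuple[float, float]
) -> tuple[float, float]:
    """Baseline-to-trough a-wave amplitude and implicit time.

    Amplitude is ``baseline − min(trace in window)`` clipped at 0; implicit
    time is the latency of that minimum.  Ties resolve to the earliest
    sample (``argmin`` convention).
    """
    lo, hi = search_window_ms
    mask = (trace.time_ms >= lo) & (trace.time_ms <= hi)
    if not mask.any():
        raise WindowError("empty a-wave search window")
    v = trace.voltage_uV[mask]
    t = trace.time_ms[mask]
    i = int(np.argmin(v))
    amp = max(0.0, baseline_uV - float(v[i]))
    return amp, float(t[i])


def measure_b_wave(
    smooth_trace: Trace, a_trough: tuple[float, float], search_window_ms: tuple[float, float]
) -> tuple[float, float]:
    """Trough-to-peak b-wave amplitude on the OP-subtracted trace.

    ``a_trough`` is (time_ms, voltage_uV) of the a-wave trough; amplitude is
    ``max(smooth in window) − trough voltage`` clipped at 0.
    """
    t0, v0 = a_trough
    lo, hi = search_window_ms
    mask = (smooth_trace.time_ms >= lo) & (smooth_trace.time_ms <= hi)
    if not mask.any():
        raise WindowError("empty b-wave search window")
    v = smooth_trace.voltage_uV[mask]
    t = smooth_trace.time_ms[mask]
    i = int(np.argmax(v))
    amp = max(0.0, float(v[i]) - v0)
    return amp, float(t[i])


def detect_op_peaks(
    op_trace: Trace,
    search_window_ms: tuple[float, float],
    min_prominence_uV: float = 5.0,
    max_peaks: int = 4,
    min_spacing_ms: float = 6.0,
) -> list[tuple[float, float]]:
    """Positive, prominence-filtered local maxima of the OP trace.

    ``min_spacing_ms`` suppresses the smaller of two peaks closer than the
    physiological OP spacing (rodent scotopic OPs run near 100 Hz, i.e.
    ~10 ms apart), which rejects noise bumps riding between true wavelets.
    Returns up to ``max_peaks`` (implicit_ms, amp_uV) pairs in time order;
    an empty list is a valid result.
    """
    lo, hi = search_window_ms
    mask = (op_trace.time_ms >= lo) & (op_trace.time_ms <= hi)
    if not mask.any():
        return []
    v = op_trace.voltage_uV[mask]
    t = op_trace.time_ms[mask]
    distance = max(1, round(min_spacing_ms / op_trace.dt_ms))
    idx, _ = sps.find_peaks(v, prominence=min_prominence_uV, distance=distance)
    idx = idx[v[idx] > 0]
    return [(float(t[i]), float(v[i])) for i in idx[:max_peaks]]


@dataclass
class ERGFeatures:
    """Waveform features of one averaged trace; missing entries are NaN."""

    baseline_uV: float = np.nan
    a_amp_uV: float = np.nan
    a_implicit_ms: float = np.nan
    b_amp_uV: float = np.nan
    b_implicit_ms: float = np.nan
    op_implicit_ms: list[float] = field(default_factory=lambda: [np.nan] * 4)
    op_amp_uV: list[float] = field(default_factory=lambda: [np.nan] * 4)
    a_fallback: bool = False


def extract_trace_features(
    trace: AveragedTrace, filt: FilterSpec = FilterSpec(), windows: Windows = Windows()
) -> ERGFeatures:
    """Run the full per-trace measurement chain.

    average (done upstream) → baseline → a-wave on the raw average →
    OP isolation → OP subtraction → b-wave on the smooth trace → OP peaks
    on the filtered trace.
    """
    f = ERGFeatures()
    f.baseline_uV = estimate_baseline(trace, windows.pre_window_ms)
    a_amp, a_time = measure_a_wave(trace, f.baseline_uV, windows.a_search_ms)
    op = isolate_ops(trace, filt)
    smooth = subtract_ops(trace, op)
    if a_amp < windows.a_min_amp_uV:
        # dim flash, no detectable a-wave: reference the b-wave to baseline
        f.a_fallback = True
        f.a_amp_uV, f.a_implicit_ms = a_amp, a_time
        trough = (0.0, f.baseline_uV)
    else:
        f.a_amp_uV, f.a_implicit_ms = a_amp, a_time
        i = int(np.searchsorted(trace.time_ms, a_time))
        trough = (a_time, float(trace.voltage_uV[i]))
    f.b_amp_uV, f.b_implicit_ms = measure_b_wave(
        smooth, trough, (trough[0], windows.b_search_end_ms)
    )
    t_first = trace.time_ms[0] + windows.edge_trim_ms
    t_last = trace.time_ms[-1] - windows.edge_trim_ms
    op_lo = max(trough[0], t_first)
    op_hi = min(f.b_implicit_ms + windows.op_window_pad_ms, t_last)
    peaks = detect_op_peaks(
        op, (op_lo, op_hi), windows.min_prominence_uV, min_spacing_ms=windows.op_min_spacing_ms
    )
    for k, (t_pk, v_pk) in enumerate(peaks):
        f.op_implicit_ms[k] = t_pk
        f.op_amp_uV[k] = v_pk
    return f


def _sweep_traces(group: pd.DataFrame) -> list[Trace]:
    traces = []
    for _, g in group.groupby("trial", sort=True):
        g = g.sort_values("time_ms", kind="mergesort")
        traces.append(Trace(g["time_ms"].to_numpy(float), g["voltage_uV"].to_numpy(float)))
    return traces


def extract_features(
    sweeps: pd.DataFrame, filt: FilterSpec = FilterSpec(), windows: Windows = Windows()
) -> pd.DataFrame:
    """Extract a feature table from a validated sweep table.

    One row per (animal, eye, luminance); provenance columns record the
    number of averaged trials, the filter settings and whether the a-trough
    fallback fired.  Deterministic and invariant to input row order.
    """
    eio.validate_sweeps(sweeps)
    rows = []
    keys = ["animal_id", "eye", "luminance_log"]
    for (animal, eye, lum), group in sweeps.groupby(keys, sort=True):
        traces = _sweep_traces(group)
        try:
            avg = average_sweeps(traces, luminance_log=lum, eye=eye, animal_id=animal)
            f = extract_trace_features(avg, filt, windows)
        except (GridMismatchError, WindowError) as exc:
            raise type(exc)(f"{exc} [animal={animal}, eye={eye}, luminance={lum}]") from exc
        rows.append(
            {
                "animal_id": animal,
                "eye": eye,
                "luminance_log": lum,
                "baseline_uV": f.baseline_uV,
                "a_amp_uV": f.a_amp_uV,
                "a_implicit_ms": f.a_implicit_ms,
                "b_amp_uV": f.b_amp_uV,
                "b_implicit_ms": f.b_implicit_ms,
                **{f"op{k+1}_implicit_ms": f.op_implicit_ms[k] for k in range(4)},
                **{f"op{k+1}_amp_uV": f.op_amp_uV[k] for k in range(4)},
                "n_trials": len(traces),
                "filter_cutoff_hz": filt.cutoff_hz,
                "filter_order": filt.order,
                "a_fallback": int(f.a_fallback),
            }
        )
    return pd.DataFrame(rows, columns=eio.FEATURE_COLUMNS)


def select_eye(per_eye_features: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Pick the analysis eye for one animal.

    The eye with the larger b-wave amplitude at the maximal flash luminance
    wins; ties break to the right eye.  Raises
    :class:`EyeSelectionError` if neither eye has a measurable b-wave there.
    """
    lum_max = per_eye_features["luminance_log"].max()
    at_max = per_eye_features[per_eye_features["luminance_log"] == lum_max]
    best_eye, best_amp = None, -np.inf
    for eye in ("right", "left"):  # right first => ties keep right
        sub = at_max[at_max["eye"] == eye]
        if sub.empty:
            continue
        amp = float(sub["b_amp_uV"].iloc[0])
        if np.isnan(amp):
            continue
        if amp > best_amp:
            best_eye, best_amp = eye, amp
    if best_eye is None:
        raise EyeSelectionError("no eye has a b-wave at the comparison luminance")
    return best_eye, per_eye_features[per_eye_features["eye"] == best_eye].copy()


def select_eyes(features: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`select_eye` per animal; returns the one-eye-per-animal table."""
    parts = []
    for _, group in features.groupby("animal_id", sort=True):
        _, chosen = select_eye(group)
        parts.append(chosen)
    return pd.concat(parts, ignore_index=True)


def luminance_response(features: pd.DataFrame) -> pd.DataFrame:
    """Per-animal a-/b-wave amplitude vs luminance, plus the maximum a-wave.

    Expects a one-eye-per-animal feature table; rows come back sorted by
    (animal, luminance) with a ``max_a_amp_uV`` column repeated per animal.
    """
    df = features.sort_values(["animal_id", "luminance_log"], kind="mergesort")
    out = df[["animal_id", "eye", "luminance_log", "a_amp_uV", "b_amp_uV"]].copy()
    out["max_a_amp_uV"] = out.groupby("animal_id")["a_amp_uV"].transform("max")
    return out.reset_index(drop=True)
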