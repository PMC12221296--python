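"""Raw-trace preprocessing: spike removal, downsampling, burst detection,
cycle segmentation, phase assignment and epoch quality control.

The analysis assumes a slowly varying membrane potential; action
potentials are stripped with a moving median, traces are decimated to the
analysis rate by anti-aliasing block averages, and the reference nerve
signal is rectified and leaky-integrated before burst-onset detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .core import (
    CURRENT_CLAMP,
    DetectionError,
    ParameterError,
    PipelineConfig,
    Recording,
    ValidationError,
)


@dataclass
class CycleSet:
    """Reference-rhythm segmentation of an epoch.

    ``onsets`` are burst-onset times (s), ``periods[k] = onsets[k+1] -
    onsets[k]``, ``cv_period`` is the coefficient of variation of the
    periods, and ``inspiratory_fraction`` the mean fraction of the cycle
    during which the integrated reference signal sits above the onset
    threshold.
    """

    onsets: np.ndarray
    periods: np.ndarray
    cv_period: float
    inspiratory_fraction: float

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)
        if self.onsets.size < 2:
            raise ValidationError("need at least 2 burst onsets")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")
        if np.any(self.periods <= 0):
            raise ValidationError("periods must be positive")

    @property
    def n_cycles(self) -> int:
        return int(self.periods.size)


@dataclass
class QCReport:
    """Outcome of the epoch quality-control criteria.

    ``passed`` is true iff ``reasons`` is empty.
    """

    passed: bool
    cv_period: float
    n_steps: int
    cycles_per_step: list
    drift_flag: bool
    drift_slope: float  # mV/min linear trend of the inter-burst baseline
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        self.passed = len(self.reasons) == 0

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "cv_period": float(self.cv_period),
            "n_steps": int(self.n_steps),
            "cycles_per_step": [int(c) for c in self.cycles_per_step],
            "drift_flag": bool(self.drift_flag),
            "drift_slope_mv_per_min": float(self.drift_slope),
            "reasons": list(self.reasons),
        }


def remove_spikes(vm: np.ndarray, window: float, sample_rate: float
                  ) -> np.ndarray:
    """Moving-median filtration of a voltage trace.

    Suppresses action-potential transients while preserving slow membrane
    potential waves.  The window shrinks symmetrically at the trace ends
    (no values are invented by padding).

    Parameters
    ----------
    window : float
        Filter window in seconds; must span at least 3 samples.
    """
    vm = np.asarray(vm, dtype=float)
    w = int(round(window * sample_rate))
    if w % 2 == 0:
        w += 1
    if w < 3:
        raise ParameterError(
            f"median window {window} s spans fewer than 3 samples "
            f"at {sample_rate} Hz"
        )
    if vm.size < 2:
        raise ParameterError("trace too short to filter")
    half = w // 2
    # interior: fixed odd window (edge mode irrelevant, overwritten below)
    out = ndimage.median_filter(vm, size=w, mode="nearest")
    # edges: symmetric shrinking windows
    n = vm.size
    for k in range(min(half, n)):
        out[k] = np.median(vm[: 2 * k + 1])
        out[n - 1 - k] = np.median(vm[n - 1 - 2 * k:])
    return out


def downsample(series: np.ndarray, from_rate: float, to_rate: float
               ) -> np.ndarray:
    """Anti-aliased decimation by block averaging.

    The rate ratio must be an integer; each output sample is the mean of
    one block of input samples, so the trace mean is preserved exactly.
    Applied to the time channel this yields the block-center times.
    """
    if to_rate > from_rate:
        raise ParameterError("to_rate must not exceed from_rate")
    ratio = from_rate / to_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 * factor:
        raise ParameterError(
            f"rate ratio {from_rate}/{to_rate} is not an integer"
        )
    series = np.asarray(series, dtype=float)
    n_blocks = series.size // factor
    if n_blocks == 0:
        raise ParameterError("series shorter than one block")
    return series[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)


def rectify_integrate(ref: np.ndarray, tau: float, sample_rate: float
                      ) -> np.ndarray:
    """Rectify and leaky-integrate a nerve signal.

    First-order low-pass of the absolute value:
    ``y[k] = y[k-1] + (dt/tau) * (|ref[k]| - y[k-1])`` with
    ``y[0] = |ref[0]|``.  Output is non-negative.
    """
    dt = 1.0 / sample_rate
    if tau <= dt:
        raise ParameterError("integrator tau must exceed the sample interval")
    x = np.abs(np.asarray(ref, dtype=float))
    alpha = dt / tau
    # y[k] = (1-alpha) y[k-1] + alpha x[k]  ->  IIR filter with state
    b = [alpha]
    a = [1.0, -(1.0 - alpha)]
    zi = np.array([(1.0 - alpha) * x[0]])
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def _upward_crossings(t, y, threshold):
    """Sub-sample times where y crosses threshold from below."""
    above = y >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - y[idx]) / (y[idx + 1] - y[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def detect_burst_onsets(time: np.ndarray, integrated: np.ndarray,
                        threshold_frac: float = 0.10,
                        min_interval: Optional[float] = None) -> CycleSet:
    """Detect reference-burst onsets in a rectified/integrated signal.

    The baseline is the 5th percentile of the signal.  Burst amplitude is
    estimated in two passes: a provisional detection using the global
    maximum, then a refinement with the median of per-burst peaks.  The
    onset is the upward crossing of ``baseline + threshold_frac *
    (amplitude - baseline)``; crossings closer than ``min_interval`` to
    the previous onset are suppressed (default: half the median period
    from the first pass).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(integrated, dtype=float)
    baseline = np.percentile(y, 5)
    amp = y.max() - baseline
    if amp <= 0:
        raise DetectionError("reference signal is flat")
    thr = baseline + threshold_frac * amp
    onsets = _upward_crossings(t, y, thr)
    if onsets.size < 2:
        raise DetectionError("fewer than 2 burst onsets found")
    med_period = float(np.median(np.diff(onsets)))
    if min_interval is None:
        min_interval = 0.5 * med_period
    # refine amplitude: median of per-burst peaks above baseline
    peaks = []
    bounds = np.concatenate([onsets, [t[-1] + 1e-12]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = y[(t >= a) & (t < b)]
        if seg.size:
            peaks.append(seg.max())
    amp = float(np.median(peaks)) - baseline
    if amp <= 0:
        raise DetectionError("burst amplitude not distinguishable")
    thr = baseline + threshold_frac * amp
    raw = _upward_crossings(t, y, thr)
    if raw.size < 2:
        raise DetectionError("fewer than 2 burst onsets found")
    onsets = [raw[0]]
    for x in raw[1:]:
        if x - onsets[-1] >= min_interval:
            onsets.append(x)
    onsets = np.asarray(onsets)
    if onsets.size < 2:
        raise DetectionError("fewer than 2 burst onsets after suppression")
    periods = np.diff(onsets)
    mean_p = periods.mean()
    cv = float(periods.std(ddof=1) / mean_p) if periods.size > 1 else 0.0
    # duty cycle of the reference burst within complete cycles
    span = (t >= onsets[0]) & (t < onsets[-1])
    frac = float(np.mean(y[span] >= thr)) if span.any() else float("nan")
    return CycleSet(onsets=onsets, periods=periods, cv_period=cv,
                    inspiratory_fraction=frac)


def compute_phase(t: np.ndarray, cycles: CycleSet):
    """Piece-wise linear cycle phase phi(t) = (t - t_k)/(t_{k+1} - t_k).

    Returns ``(phase, in_span)``; samples outside ``[first onset, last
    onset)`` are excluded (phase NaN, in_span False).  Within each cycle
    the phase is linear in time, equals 0 at the onset, and lies in
    [0, 1).
    """
    t = np.asarray(t, dtype=float)
    onsets = cycles.onsets
    idx = np.searchsorted(onsets, t, side="right") - 1
    in_span = (idx >= 0) & (idx < onsets.size - 1)
    if not in_span.any():
        raise ValidationError("no samples fall within the detected cycles")
    phase = np.full(t.shape, np.nan)
    k = idx[in_span]
    phase[in_span] = (t[in_span] - onsets[k]) / cycles.periods[k]
    # guard against round-off landing exactly on 1.0
    phase[in_span] = np.clip(phase[in_span], 0.0, np.nextafter(1.0, 0.0))
    return phase, in_span


def find_plateaus(t: np.ndarray, controlled: np.ndarray, tol: float):
    """Maximal runs where the controlled channel stays within ``tol``.

    Returns a list of ``(t_start, t_end, level)`` tuples.
    """
    x = np.asarray(controlled, dtype=float)
    change = np.flatnonzero(np.abs(np.diff(x)) > tol)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [x.size - 1]])
    plateaus = []
    for s, e in zip(starts, ends):
        if e > s:
            plateaus.append((t[s], t[e], float(np.median(x[s:e + 1]))))
    return plateaus


def qc_epoch(recording: Recording, cycles: CycleSet,
             config: PipelineConfig) -> QCReport:
    """Evaluate the epoch acceptance criteria.

    1. cycle-period CV below ``cv_max``;
    2. at least ``min_steps`` distinct held levels of the controlled
       channel, each held for at least ``min_cycles_per_step`` complete
       cycles;
    3. no obvious instability, operationalized as an inter-burst baseline
       Vm trend below ``drift_max`` mV/min (current clamp only; the level
       effect of the current steps is regressed out first).
    """
    reasons = []
    cv = cycles.cv_period
    if cv >= config.cv_max:
        reasons.append("cv_period")

    tol = (config.plateau_tol if recording.clamp_mode == CURRENT_CLAMP
           else config.level_tol_vc)
    plateaus = find_plateaus(recording.time, recording.controlled, tol)
    onsets = cycles.onsets
    qualifying = []
    cycles_per_step = []
    for (t0, t1, level) in plateaus:
        # cycles held at this level: >= 90% of the cycle inside the
        # plateau (the onset definition lags the level switches slightly)
        start = np.maximum(cycles.onsets[:-1], t0)
        end = np.minimum(cycles.onsets[1:], t1)
        overlap = np.clip(end - start, 0.0, None) / cycles.periods
        n_cyc = int(np.sum(overlap >= 0.9))
        if n_cyc >= config.min_cycles_per_step:
            qualifying.append(level)
            cycles_per_step.append(n_cyc)
    n_steps = np.unique(np.round(np.asarray(qualifying) / tol)).size \
        if qualifying else 0
    if n_steps < config.min_steps:
        reasons.append("min_steps")

    drift_slope = 0.0
    drift_flag = False
    if recording.clamp_mode == CURRENT_CLAMP and cycles.n_cycles >= 3:
        # per-cycle baseline = median Vm over the last 20% of each cycle
        t = recording.time
        tb, vb, ib = [], [], []
        for k in range(cycles.n_cycles):
            a = onsets[k] + 0.8 * cycles.periods[k]
            b = onsets[k + 1]
            m = (t >= a) & (t < b)
            if m.any():
                tb.append(0.5 * (a + b))
                vb.append(np.median(recording.vm[m]))
                ib.append(np.median(recording.i_inj[m]))
        if len(tb) >= 3:
            X = np.column_stack([np.ones(len(tb)), tb, ib])
            beta, *_ = np.linalg.lstsq(X, np.asarray(vb), rcond=None)
            drift_slope = float(beta[1] * 60.0)  # mV/s -> mV/min
            drift_flag = abs(drift_slope) > config.drift_max
            if drift_flag:
                reasons.append("drift")

    return QCReport(passed=not reasons, cv_period=cv, n_steps=n_steps,
                    cycles_per_step=cycles_per_step, drift_flag=drift_flag,
                    drift_slope=drift_slope, reasons=reasons)
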