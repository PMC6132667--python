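"""Field-potential scoring: peak-to-peak amplitude, population spikes,
input/output curves and the return-to-baseline check.

Peak-to-peak amplitude is the distance from the most negative to the most
positive peak within the 25 ms post-stimulus scoring window.  Population
spikes — the summed action potentials of many synchronously firing
neurons — appear as brief (~1-2 ms) sharp negative deflections riding on
the slow wave.  Published work scored them by visual inspection; this
module commits to an explicit operationalization: a derivative-threshold
detector.  The first difference of the trace is compared against
``k_sd`` x the baseline first-difference SD; contiguous supra-threshold
runs (runs closer than 1 ms are merged into one event) count as a spike
when the event is fast (duration <= 3 ms), negative-going, and sustained
for at least 0.2 ms — the minimum-run rule keeps single noise samples from
counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .recordings import FieldPotentialTrace

#: post-stimulus scoring horizon, ms
WINDOW_MS = 25.0
BASELINE_MS = 50.0
#: fallback derivative threshold (mV per sample) when the baseline is
#: noise-free and k_sd * SD would be zero
ABS_THRESHOLD_MV = 0.1


@dataclass
class SpikeScore:
    """Population-spike outcome for one slice (or one trace)."""

    slice_id: str
    condition: str
    intensity_percent: int
    n_spikes: int
    spike_times_ms: list = field(default_factory=list)

    @property
    def has_spike(self) -> bool:
        return self.n_spikes >= 1


@dataclass
class IOCurve:
    """Input/output relation: mean +- SEM amplitude per stimulation intensity."""

    condition: str
    layer: str
    points: list   # (intensity_percent, mean_mV, sem_mV), intensities ascending


def _window_slice(trace: FieldPotentialTrace, window_ms: float):
    dt = trace.sampling_interval
    onset = trace.stimulus_onset
    n = int(round(window_ms / dt))
    return slice(onset + 1, onset + n + 1)


def fp_amplitude(trace: FieldPotentialTrace,
                 window_ms: float = WINDOW_MS) -> float:
    """Peak-to-peak amplitude (mV): max - min over (0, window_ms] post-stimulus."""
    seg = trace.voltages[_window_slice(trace, window_ms)]
    if seg.size == 0:
        raise InvalidParameterError("scoring window is empty")
    return float(seg.max() - seg.min())


def detect_population_spikes(trace: FieldPotentialTrace,
                             k_sd: float = 4.0,
                             detection_window_ms: float = WINDOW_MS,
                             baseline_ms: float = BASELINE_MS,
                             min_run_ms: float = 0.2,
                             max_run_ms: float = 3.0,
                             merge_ms: float = 1.0) -> SpikeScore:
    """Derivative-threshold population-spike detector.

    Candidate events are contiguous runs of ``|dV| > k_sd * SD(baseline dV)``
    within the post-stimulus detection window, merged when separated by less
    than ``merge_ms`` (the falling and rising edge of one spike).  An event
    counts as a spike when its total duration is at most ``max_run_ms``, it
    opens with a negative-going deflection, and its negative-going phase
    lasts at least ``min_run_ms``.
    """
    if detection_window_ms > WINDOW_MS:
        raise InvalidParameterError(
            f"detection window must be <= {WINDOW_MS} ms post-stimulus")
    dt = trace.sampling_interval
    onset = trace.stimulus_onset
    v = trace.voltages
    dv = np.diff(v)

    nb = int(round(baseline_ms / dt))
    base_dv = dv[max(onset - nb, 0):onset - 1]
    sd = base_dv.std()
    thr = k_sd * sd
    if thr < ABS_THRESHOLD_MV:
        # (near-)noise-free baseline: k_sd * SD would flag arbitrarily slow
        # deflections; fall back to an absolute slope floor
        warnings.warn("baseline derivative variance (near) zero; "
                      "falling back to absolute threshold", stacklevel=2)
        thr = ABS_THRESHOLD_MV

    nw = int(round(detection_window_ms / dt))
    # dv[i] is the step from sample i to i+1; assign it the later time
    det = slice(onset, onset + nw)
    d = dv[det]
    above = np.abs(d) > thr

    # contiguous runs of supra-threshold samples
    runs = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by < merge_ms into single events
    gap = int(round(merge_ms / dt))
    events = []
    for run in runs:
        if events and run[0] - events[-1][1] - 1 < gap:
            events[-1] = (events[-1][0], run[1])
        else:
            events.append(run)

    min_run = max(int(round(min_run_ms / dt)), 1)
    max_run = int(round(max_run_ms / dt))
    n_spikes = 0
    spike_times = []
    for i0, i1 in events:
        if i1 - i0 + 1 > max_run:
            continue
        if d[i0] >= 0:
            continue    # must open negative-going
        seg = d[i0:i1 + 1]
        neg = (seg < -thr).astype(int)
        # longest contiguous negative-going stretch
        best = run_len = 0
        for flag in neg:
            run_len = run_len + 1 if flag else 0
            best = max(best, run_len)
        if best < min_run:
            continue
        n_spikes += 1
        tip = i0 + int(np.argmin(seg))
        spike_times.append(float((tip + 1) * dt))
    return SpikeScore(slice_id=trace.slice_id, condition=trace.condition,
                      intensity_percent=trace.stimulation.intensity_percent,
                      n_spikes=n_spikes, spike_times_ms=spike_times)


def slice_spike_scores(traces, **detector_kwargs) -> list[SpikeScore]:
    """One SpikeScore per (slice, intensity): a slice counts as spiking when
    any of its electrodes saw a spike."""
    grouped: dict = {}
    for tr in traces:
        key = (tr.slice_id, tr.stimulation.intensity_percent)
        score = detect_population_spikes(tr, **detector_kwargs)
        if key not in grouped or score.n_spikes > grouped[key].n_spikes:
            grouped[key] = score
    return [grouped[k] for k in sorted(grouped)]


def spike_fraction(scores) -> dict[int, float]:
    """Percent of slices with >= 1 spike, per stimulation intensity."""
    scores = list(scores)
    if not scores:
        raise InvalidParameterError("no spike scores")
    out: dict[int, float] = {}
    for intensity in sorted({s.intensity_percent for s in scores}):
        group = [s for s in scores if s.intensity_percent == intensity]
        out[intensity] = 100.0 * sum(s.has_spike for s in group) / len(group)
    return out


def io_curve(amplitudes: pd.DataFrame, condition: str, layer: str) -> IOCurve:
    """Input/output curve from a tidy table with columns
    ``intensity_percent`` and ``amplitude_mv`` (one row per slice).
    Monotonicity is not enforced — responses saturate."""
    points = []
    for intensity, grp in amplitudes.groupby("intensity_percent"):
        vals = grp["amplitude_mv"].to_numpy(dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        points.append((int(intensity), float(vals.mean()), float(sem)))
    points.sort(key=lambda p: p[0])
    return IOCurve(condition=condition, layer=layer, points=points)


def baseline_return(trace: FieldPotentialTrace, tol_k: float = 3.0,
                    baseline_ms: float = BASELINE_MS):
    """Has the voltage returned to baseline 25 ms after the stimulus?

    Compares the mean over the 25-30 ms post-stimulus window against the
    pre-stimulus baseline; the tolerance is ``tol_k`` x the baseline SD
    (with a small absolute floor for noise-free traces).  Returns
    ``(returned, residual_mv)``.
    """
    dt = trace.sampling_interval
    onset = trace.stimulus_onset
    nb = int(round(baseline_ms / dt))
    i0 = onset + int(round(25.0 / dt))
    i1 = onset + int(round(30.0 / dt))
    if i1 > trace.voltages.size:
        raise InvalidParameterError("trace too short for the 25-30 ms check")
    baseline = trace.voltages[onset - nb:onset]
    residual = float(trace.voltages[i0:i1].mean() - baseline.mean())
    tol = max(tol_k * baseline.std(), 1e-3)
    return abs(residual) <= tol, residual
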