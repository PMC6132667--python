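"""VSD measurement pipeline: dI/I, trial averaging, layer signals, maps.

The optical activity measure is the fractional fluorescence change
dI/I = (I_rest - I(t)) / I_rest, with I_rest the per-diode mean intensity
over the 50 ms preceding the stimulus.  dI/I is computed per trial (each
trial uses its own resting level, which makes the measure robust to slow
bleaching between trials), then the three stimulus-locked trials are
averaged.  Layer read-outs average six adjacent diodes: the in-band site
nearest the recording electrode plus its five nearest in-band neighbors.
Amplitude is the baseline-subtracted peak within a post-stimulus search
window; latency is the stimulus-to-peak time at sample resolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import (ConfigurationError, DegenerateInputError,
                     InvalidParameterError)
from .geometry import DiodeArrayGeometry
from .recordings import VSDRecording

BASELINE_MS = 50.0
#: default post-stimulus search window for the response peak; generously
#: contains every observed stimulus-to-peak time (<= 12.4 ms) while
#: excluding late drift
SEARCH_MS = 100.0


@dataclass
class FractionalSignal:
    """dI/I matrix for one slice (unitless fractions; report as %)."""

    values: np.ndarray            # (n_active_sites, n_samples), fraction
    stimulus_onset: int
    sampling_interval: float      # ms
    slice_id: str
    condition: str
    n_trials_averaged: int = 1
    geometry_ref: str = "default-464"

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


class PeakMeasure(NamedTuple):
    amplitude: float      # baseline-subtracted peak, input units
    latency_ms: float     # stimulus-to-peak time
    peak_sample: int
    flagged: bool         # True when the trace is flat (no peak defined)


def fractional_fluorescence(recording: VSDRecording,
                            baseline_ms: float = BASELINE_MS) -> FractionalSignal:
    """Convert raw diode intensities to dI/I = (I_rest - I(t)) / I_rest."""
    dt = recording.sampling_interval
    nb = int(round(baseline_ms / dt))
    onset = recording.stimulus_onset
    if onset - nb < 0:
        raise InvalidParameterError(
            f"stimulus_onset leaves no room for a {baseline_ms} ms baseline")
    i_rest = recording.intensities[:, onset - nb:onset].mean(axis=1)
    if not (i_rest > 0).all():
        raise DegenerateInputError("non-positive resting intensity I_rest")
    values = (i_rest[:, None] - recording.intensities) / i_rest[:, None]
    return FractionalSignal(values=values, stimulus_onset=onset,
                            sampling_interval=dt, slice_id=recording.slice_id,
                            condition=recording.condition,
                            n_trials_averaged=1,
                            geometry_ref=recording.geometry_ref)


def average_trials(signals) -> FractionalSignal:
    """Element-wise mean of stimulus-locked fractional signals (typically 3)."""
    signals = list(signals)
    if not signals:
        raise InvalidParameterError("no signals to average")
    first = signals[0]
    for s in signals[1:]:
        if s.values.shape != first.values.shape:
            raise InvalidParameterError("trial shapes differ")
        if s.stimulus_onset != first.stimulus_onset:
            raise InvalidParameterError("trial stimulus onsets differ")
    mean = np.mean([s.values for s in signals], axis=0)
    return dataclasses.replace(
        first, values=mean,
        n_trials_averaged=sum(s.n_trials_averaged for s in signals))


def select_layer_diodes(geometry: DiodeArrayGeometry, layer: str,
                        electrode_position) -> np.ndarray:
    """Rows (into the active-site matrix) of the six-diode layer group.

    Seed diode = in-band active site nearest ``electrode_position`` (mm),
    plus its five nearest in-band neighbors; Euclidean distance, ties broken
    by site_id.
    """
    active_rows = geometry.active_rows
    in_band = geometry.band_mask_active(layer)
    idx = np.flatnonzero(in_band)                       # active-row indices
    if idx.size < 6:
        raise ConfigurationError(
            f"layer {layer!r} has only {idx.size} active sites (< 6)")
    pos = geometry.position[active_rows[idx]]
    ids = geometry.site_id[active_rows[idx]]
    target = np.asarray(electrode_position, dtype=float)
    d = np.linalg.norm(pos - target, axis=1)
    seed_local = np.lexsort((ids, d))[0]
    d_seed = np.linalg.norm(pos - pos[seed_local], axis=1)
    order = np.lexsort((ids, d_seed))
    return idx[order[:6]]


def layer_signal(signal: FractionalSignal, geometry: DiodeArrayGeometry,
                 layer: str, electrode_position) -> np.ndarray:
    """Mean dI/I time series over the six-diode group of ``layer``."""
    rows = select_layer_diodes(geometry, layer, electrode_position)
    return signal.values[rows].mean(axis=0)


def amplitude_latency(trace: np.ndarray, stimulus_onset: int,
                      sampling_interval: float,
                      baseline_ms: float = BASELINE_MS,
                      search_ms: float = SEARCH_MS) -> PeakMeasure:
    """Baseline-subtracted peak amplitude and stimulus-to-peak latency.

    Baseline is the mean over the ``baseline_ms`` window preceding the
    stimulus; the peak is the maximum of (trace - baseline) over the
    half-open post-stimulus window ``(onset, onset + search_ms]``.  Latency
    is reported at sample resolution.  A flat search window yields amplitude
    0 with ``flagged=True`` and the latency of the first window sample.
    """
    trace = np.asarray(trace, dtype=float)
    nb = int(round(baseline_ms / sampling_interval))
    ns = int(round(search_ms / sampling_interval))
    if stimulus_onset - nb < 0 or stimulus_onset + ns >= trace.size:
        raise InvalidParameterError("windows exceed trace extent")
    baseline = trace[stimulus_onset - nb:stimulus_onset].mean()
    seg = trace[stimulus_onset + 1:stimulus_onset + ns + 1] - baseline
    if np.all(seg == seg[0]):
        return PeakMeasure(amplitude=0.0,
                           latency_ms=sampling_interval,
                           peak_sample=stimulus_onset + 1, flagged=True)
    k = int(np.argmax(seg))
    peak_sample = stimulus_onset + 1 + k
    return PeakMeasure(amplitude=float(seg[k]),
                       latency_ms=(k + 1) * sampling_interval,
                       peak_sample=peak_sample, flagged=False)


def normalize_to_reference(values: np.ndarray, reference: float) -> np.ndarray:
    """Scale a signal so the reference level maps to 1.0.

    Display transform only (e.g. scaling pseudocolor maps to the control
    level of 0.34% dI/I); never applied before measurement.
    """
    if not reference > 0:
        raise InvalidParameterError("reference must be > 0")
    return np.asarray(values, dtype=float) / reference


def activity_map(signal: FractionalSignal, geometry: DiodeArrayGeometry,
                 frame_samples=None):
    """Per-site scalars for pseudocolor frames, scaled to the session maximum.

    Returns ``(frames, positions)`` with ``frames`` of shape
    ``(n_frames, n_active_sites)`` in [-1, 1] and ``positions`` the active
    site coordinates (mm) at which to render the hexagonal cells.
    """
    if frame_samples is None:
        frame_samples = np.arange(signal.n_samples)
    frame_samples = np.asarray(frame_samples, dtype=int)
    session_max = np.abs(signal.values).max()
    scale = session_max if session_max > 0 else 1.0
    frames = signal.values[:, frame_samples].T / scale
    return frames, geometry.position[geometry.active_rows]


def layer_time_heatmap(signals, geometry: DiodeArrayGeometry,
                       n_depth_bins: int = 6) -> np.ndarray:
    """Depth-binned mean dI/I over time, averaged across slices.

    Sites are binned by their cortical-depth coordinate into
    ``n_depth_bins`` contiguous bins (default 6, one per anatomical layer);
    rows are ordered shallow (supragranular) to deep.  All signals must be
    stimulus-aligned and share a shape.
    """
    signals = list(signals)
    if not signals:
        raise InvalidParameterError("empty cohort")
    if geometry.depth is None:
        raise ConfigurationError("geometry needs layer bands assigned")
    if n_depth_bins < 1:
        raise InvalidParameterError("n_depth_bins must be >= 1")
    shape = signals[0].values.shape
    for s in signals[1:]:
        if s.values.shape != shape:
            raise InvalidParameterError("cohort signals differ in shape")
        if s.stimulus_onset != signals[0].stimulus_onset:
            raise InvalidParameterError("cohort signals differ in onset")
    mean_signal = np.mean([s.values for s in signals], axis=0)

    depth = geometry.depth[geometry.active_rows]
    edges = np.linspace(depth.min(), depth.max(), n_depth_bins + 1)
    # np.digitize puts the maximum into the overflow bin; clip it back
    which = np.clip(np.digitize(depth, edges) - 1, 0, n_depth_bins - 1)
    heatmap = np.full((n_depth_bins, shape[1]), np.nan)
    for b in range(n_depth_bins):
        rows = which == b
        if rows.any():
            heatmap[b] = mean_signal[rows].mean(axis=0)
    return heatmap
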