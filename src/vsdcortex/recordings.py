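"""In-memory containers for single-trial recordings.

A VSD trial is a dense (active sites x samples) matrix of raw fluorescence
intensities in arbitrary units, acquired at 1.274 ms per sample with at most
1024 samples (1024 x 1.274 ms ~ 1304.6 ms, the maximal exposure).  Field
potentials are single-electrode voltage traces (mV) labeled with the cortical
layer the electrode sat in.  Stimulation metadata travels with every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .geometry import INFRA, SUPRA

#: VSD acquisition interval, ms
SAMPLING_MS = 1.274
#: maximal number of VSD samples per trial
MAX_SAMPLES = 1024
#: minimal stimulus-onset sample (room for the 50 ms baseline window)
MIN_ONSET_SAMPLES = 40

INTENSITY_LEVELS = (10, 50, 100)
DISTANCES = ("short", "long")
#: stimulation-electrode position implied by its distance from A1
DISTANCE_POSITION = {"short": "rostral", "long": "caudal"}


@dataclass(frozen=True)
class StimulusSpec:
    """Electrical stimulation of the thalamocortical fiber tract.

    ``intensity_percent`` is relative to the maximal pulse amplitude
    (100% ~ 1 mA); ``electrode_distance`` distinguishes the rostral (short)
    and caudal (long) stimulation positions within the internal capsule.
    """

    intensity_percent: int
    electrode_distance: str = "short"
    pulse_width_us: float = 150.0
    position: str | None = None

    def __post_init__(self):
        if self.intensity_percent not in INTENSITY_LEVELS:
            raise InvalidParameterError(
                f"intensity_percent must be one of {INTENSITY_LEVELS}, "
                f"got {self.intensity_percent}")
        if self.electrode_distance not in DISTANCES:
            raise InvalidParameterError(
                f"electrode_distance must be one of {DISTANCES}")
        if self.position is None:
            object.__setattr__(self, "position",
                               DISTANCE_POSITION[self.electrode_distance])


@dataclass
class VSDRecording:
    """One stimulus-locked VSD trial (raw intensities, strictly positive)."""

    intensities: np.ndarray          # (n_active_sites, n_samples), a.u.
    stimulus_onset: int              # sample index of pulse onset
    stimulation: StimulusSpec
    slice_id: str
    condition: str
    trial_index: int = 1             # 1..3
    sampling_interval: float = SAMPLING_MS   # ms
    geometry_ref: str = "default-464"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise InvalidParameterError("intensities must be 2-D (sites x samples)")
        if self.intensities.shape[1] > MAX_SAMPLES:
            raise InvalidParameterError(
                f"sample count {self.intensities.shape[1]} exceeds {MAX_SAMPLES}")
        if self.stimulus_onset < MIN_ONSET_SAMPLES:
            raise InvalidParameterError(
                f"stimulus_onset must be >= {MIN_ONSET_SAMPLES} samples")
        if not np.isfinite(self.intensities).all():
            raise InvalidParameterError("intensities must be finite")
        if not (self.intensities > 0).all():
            raise InvalidParameterError("intensities must be strictly positive")
        if not 1 <= int(self.trial_index) <= 3:
            raise InvalidParameterError("trial_index must be 1..3")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]


@dataclass
class FieldPotentialTrace:
    """One electrode's evoked field potential (mV)."""

    voltages: np.ndarray             # (n_samples,), mV
    stimulus_onset: int
    layer: str                       # supragranular | infragranular
    stimulation: StimulusSpec
    slice_id: str
    condition: str
    sampling_interval: float = 0.1   # ms

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 1:
            raise InvalidParameterError("voltages must be 1-D")
        if not np.isfinite(self.voltages).all():
            raise InvalidParameterError("voltages must be finite")
        if self.layer not in (SUPRA, INFRA):
            raise InvalidParameterError(f"unknown layer: {self.layer!r}")
        post_ms = (self.voltages.size - 1 - self.stimulus_onset) * self.sampling_interval
        if post_ms < 25.0:
            # the return-to-baseline check needs at least 25 ms after the pulse
            raise InvalidParameterError(
                f"trace covers only {post_ms:.1f} ms post-stimulus (< 25 ms)")

    @property
    def n_samples(self) -> int:
        return self.voltages.size
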