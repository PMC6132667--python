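"""Forward models generating synthetic VSD trials, FP traces and behavior.

The generators emulate the statistical structure the analysis pipeline
assumes, so that every measurement stage is testable by parameter recovery:

* **VSD trials.**  Raw diode intensities are ``I_rest * (1 - r(t, site)) +
  noise`` — membrane depolarization reduces RH-795 emission, so with the
  fractional-fluorescence convention dI/I = (I_rest - I(t)) / I_rest the
  evoked response ``r`` comes out positive.  ``r`` is an alpha-function
  kernel per layer band: a fast transient in the supragranular band
  (tau = 4 ms) and a more sustained wave in the infragranular band
  (tau = 7 ms), reproducing the transient-then-sustained laminar activation
  sequence of the healthy auditory cortex.  Each slice draws its peak dI/I
  and its stimulus-to-peak latency from the preset; the kernel is placed so
  that its peak falls on the acquisition grid (1.274 ms), making zero-noise
  recovery exact.
* **FP traces.**  A biphasic slow wave (two opposite-sign Gaussians,
  normalized on the sample grid so the peak-to-peak distance equals the
  drawn amplitude exactly) with optional 1-2 superimposed fast negative
  transients — the population spikes — drawn with the preset per-intensity
  probability.  Traces return to baseline well before the 25 ms
  post-stimulus assessment horizon.
* **Behavior.**  Per-animal freezing percentages for the neutral (2.5 kHz)
  and conditioned (10 kHz) tone, drawn from Beta distributions
  moment-matched to the preset (mean, SD) through a Gaussian copula that
  shares a latent animal effect across the two tones (paired structure).

All randomness derives from one master seed through counter-based
``SeedSequence`` spawn keys, so cohorts are bit-reproducible and growing a
cohort does not reshuffle earlier slices.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidParameterError
from .geometry import INFRA, SUPRA, DiodeArrayGeometry, default_array
from .presets import ConditionPreset, TONES
from .recordings import (SAMPLING_MS, FieldPotentialTrace, StimulusSpec,
                         VSDRecording)

#: resting light level, arbitrary fluorescence units
I_REST = 1500.0
#: alpha-kernel time constants per layer band (ms): transient supragranular,
#: sustained infragranular
TAU_MS = {SUPRA: 4.0, INFRA: 7.0}
#: default VSD trial length and stimulus onset (samples)
N_SAMPLES = 1024
STIM_ONSET = 100

#: FP trace discretization: 10 kHz sampling, 50 ms baseline, 60 ms post-stim
FP_DT_MS = 0.1
FP_ONSET = 500
FP_N_SAMPLES = 1101

#: FP slow-wave shape: negative Gaussian (depth 1, center 10 ms, sigma 4 ms)
#: plus positive Gaussian (0.9, 16.5 ms, 3.8 ms); amplitudes rescale this shape
_W_NEG = (1.0, 10.0, 4.0)
_W_POS = (0.9, 16.5, 3.8)
#: population-spike transient: Gaussian sigma (ms) and depth rule (mV)
SPIKE_SIGMA_MS = 0.3
SPIKE_DEPTH_MIN_MV = 0.7
SPIKE_DEPTH_MAX_MV = 1.0
SPIKE_DEPTH_FRACTION = 0.35

# stream purposes for counter-based seeding
_VSD_PARAMS, _VSD_NOISE, _FP_PARAMS, _FP_NOISE, _FP_SPIKE, _BEHAV = range(1, 7)
_ICODE = {10: 0, 50: 1, 100: 2}
_DCODE = {"short": 0, "long": 1}
_LCODE = {SUPRA: 0, INFRA: 1}


def _stream(seed: int, label: str, *key) -> np.random.Generator:
    # the preset label enters the entropy so that different experimental
    # groups are statistically independent cohorts (between-group tests
    # assume independence), while (preset, seed) remains bit-reproducible
    label_code = zlib.crc32(label.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence(entropy=[int(seed), label_code],
                                spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class BehaviorSession:
    """One animal x tone freezing read-out (percent of scored time immobile)."""

    animal_id: str
    condition: str
    tone: str
    freezing_percent: float

    def __post_init__(self):
        if not 0.0 <= self.freezing_percent <= 100.0:
            raise InvalidParameterError("freezing_percent outside [0, 100]")


# ---------------------------------------------------------------------------
# slice-level parameter draws (shared across the three trials of a slice)

def draw_slice_params(preset: ConditionPreset, stimulation: StimulusSpec,
                      slice_index: int, seed: int) -> dict:
    """Per-slice generative draws for one (slice, intensity, distance).

    Returns ``{layer: {"amp_pct": ..., "latency_ms": ...}}``.  Amplitudes are
    normal draws clipped at 0; latencies are clipped so the response kernel
    cannot begin before the stimulus.
    """
    intensity = stimulation.intensity_percent
    if intensity not in _ICODE:
        raise InvalidParameterError(f"unknown stimulation intensity {intensity}")
    rng = _stream(seed, preset.label, _VSD_PARAMS, slice_index, _ICODE[intensity],
                  _DCODE[stimulation.electrode_distance])
    out = {}
    for layer in (SUPRA, INFRA):
        am, asd = preset.vsd_amp[layer][intensity]
        lm, lsd = preset.latency_ms[layer][stimulation.electrode_distance]
        amp = max(0.0, rng.normal(am, asd))
        lat = rng.normal(lm, lsd)
        lat = max(lat, TAU_MS[layer] + SAMPLING_MS)
        out[layer] = {"amp_pct": float(amp), "latency_ms": float(lat)}
    return out


def _alpha_kernel(t_ms: np.ndarray, tau: float) -> np.ndarray:
    """Alpha function (t/tau)*exp(1 - t/tau), peak value 1 at t = tau."""
    s = np.where(t_ms > 0, t_ms / tau, 0.0)
    return np.where(t_ms > 0, s * np.exp(1.0 - s), 0.0)


def generate_vsd_trial(preset: ConditionPreset,
                       geometry: DiodeArrayGeometry,
                       stimulation: StimulusSpec,
                       slice_index: int,
                       trial_index: int,
                       seed: int,
                       slice_id: str | None = None,
                       stimulus_onset: int = STIM_ONSET,
                       n_samples: int = N_SAMPLES) -> VSDRecording:
    """One stimulus-locked VSD trial for one slice.

    The three trials of a slice share the slice-level parameter draws and
    differ only in their additive diode noise.
    """
    if geometry.depth is None:
        raise InvalidParameterError("geometry needs layer bands assigned")
    params = draw_slice_params(preset, stimulation, slice_index, seed)
    slice_id = slice_id or f"{preset.label}-s{slice_index:03d}"

    t_rel = (np.arange(n_samples) - stimulus_onset) * SAMPLING_MS
    active_rows = geometry.active_rows
    band_of_active = geometry.layer_band[active_rows]
    r = np.zeros((active_rows.size, n_samples))
    for layer in (SUPRA, INFRA):
        p = params[layer]
        tau = TAU_MS[layer]
        # snap the drawn peak time to the acquisition grid so the sampled
        # kernel attains its analytic maximum exactly
        lat_snap = round(p["latency_ms"] / SAMPLING_MS) * SAMPLING_MS
        kernel = _alpha_kernel(t_rel - (lat_snap - tau), tau)
        r[band_of_active == layer] = (p["amp_pct"] / 100.0) * kernel

    intensities = I_REST * (1.0 - r)
    if preset.vsd_noise_pct > 0:
        rng = _stream(seed, preset.label, _VSD_NOISE, slice_index,
                      _ICODE[stimulation.intensity_percent],
                      _DCODE[stimulation.electrode_distance], trial_index)
        intensities = intensities + I_REST * (preset.vsd_noise_pct / 100.0) \
            * rng.standard_normal(intensities.shape)
    return VSDRecording(intensities=intensities, stimulus_onset=stimulus_onset,
                        stimulation=stimulation, slice_id=slice_id,
                        condition=preset.label, trial_index=trial_index)


# ---------------------------------------------------------------------------
# field potentials

def _fp_wave_shape(t_rel: np.ndarray) -> np.ndarray:
    """Unit slow-wave shape: biphasic, zero for t <= 0, peak-to-peak 1 over
    the (0, 25] ms scoring window on this exact sample grid."""
    a, c, s = _W_NEG
    w = -a * np.exp(-((t_rel - c) / s) ** 2)
    a, c, s = _W_POS
    w = w + a * np.exp(-((t_rel - c) / s) ** 2)
    w = np.where(t_rel > 0, w, 0.0)
    win = (t_rel > 0) & (t_rel <= 25.0)
    return w / (w[win].max() - w[win].min())


def draw_fp_params(preset: ConditionPreset, layer: str,
                   stimulation: StimulusSpec, slice_index: int,
                   seed: int) -> dict:
    """Per-trace FP draws: peak-to-peak amplitude and spike ground truth.

    Spike occurrence is drawn from a stream keyed without the layer, so the
    supra- and infragranular electrodes of a slice see the same network
    event.
    """
    intensity = stimulation.intensity_percent
    if intensity not in _ICODE:
        raise InvalidParameterError(f"unknown stimulation intensity {intensity}")
    rng = _stream(seed, preset.label, _FP_PARAMS, slice_index, _ICODE[intensity],
                  _DCODE[stimulation.electrode_distance], _LCODE[layer])
    mean, sd = preset.fp_amp[layer][intensity]
    amp = max(0.0, rng.normal(mean, sd))

    rng_sp = _stream(seed, preset.label, _FP_SPIKE, slice_index, _ICODE[intensity],
                     _DCODE[stimulation.electrode_distance])
    has_spike = rng_sp.random() < preset.spike_prob[intensity]
    spike_times = []
    if has_spike:
        n_sp = 1 if rng_sp.random() < 0.6 else 2
        t1 = rng_sp.uniform(3.5, 4.5)
        spike_times = [t1]
        if n_sp == 2:
            spike_times.append(t1 + rng_sp.uniform(2.2, 2.6))
    depth = float(np.clip(SPIKE_DEPTH_FRACTION * amp,
                          SPIKE_DEPTH_MIN_MV, SPIKE_DEPTH_MAX_MV))
    return {"amp_mv": float(amp), "spike_times_ms": spike_times,
            "spike_depth_mv": depth}


def generate_fp_trace(preset: ConditionPreset, layer: str,
                      stimulation: StimulusSpec, slice_index: int, seed: int,
                      slice_id: str | None = None,
                      return_truth: bool = False):
    """One evoked field potential for one electrode.

    With ``return_truth=True`` also returns the generative ground truth
    (peak-to-peak amplitude, spike times) for detector validation.
    """
    params = draw_fp_params(preset, layer, stimulation, slice_index, seed)
    slice_id = slice_id or f"{preset.label}-s{slice_index:03d}"

    t_rel = (np.arange(FP_N_SAMPLES) - FP_ONSET) * FP_DT_MS
    v = params["amp_mv"] * _fp_wave_shape(t_rel)
    for ts in params["spike_times_ms"]:
        v = v - params["spike_depth_mv"] * np.exp(
            -((t_rel - ts) / SPIKE_SIGMA_MS) ** 2)
    if preset.fp_noise_mv > 0:
        rng = _stream(seed, preset.label, _FP_NOISE, slice_index,
                      _ICODE[stimulation.intensity_percent],
                      _DCODE[stimulation.electrode_distance], _LCODE[layer])
        v = v + preset.fp_noise_mv * rng.standard_normal(v.shape)
    trace = FieldPotentialTrace(voltages=v, stimulus_onset=FP_ONSET,
                                layer=layer, stimulation=stimulation,
                                slice_id=slice_id, condition=preset.label,
                                sampling_interval=FP_DT_MS)
    return (trace, params) if return_truth else trace


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(preset: ConditionPreset,
                    geometry: DiodeArrayGeometry | None = None,
                    n_slices: int | None = None,
                    intensities=(50,),
                    seed: int = 0,
                    electrode_distance: str = "short",
                    n_trials: int = 3):
    """Generate a full slice cohort: per slice x intensity, ``n_trials`` VSD
    trials plus one FP trace per layer.  Returns ``(geometry, recordings,
    traces)`` — the in-memory form of a recording bundle."""
    geometry = geometry if geometry is not None else default_array()
    n_slices = n_slices if n_slices is not None else preset.n_slices
    if n_slices < 1:
        raise InvalidParameterError("n_slices must be >= 1")
    recordings, traces = [], []
    for i in range(n_slices):
        for intensity in intensities:
            stim = StimulusSpec(intensity_percent=intensity,
                                electrode_distance=electrode_distance)
            for trial in range(1, n_trials + 1):
                recordings.append(generate_vsd_trial(
                    preset, geometry, stim, i, trial, seed))
            for layer in (SUPRA, INFRA):
                traces.append(generate_fp_trace(preset, layer, stim, i, seed))
    return geometry, recordings, traces


def generate_behavior_cohort(preset: ConditionPreset,
                             n_animals: int | None = None,
                             seed: int = 0,
                             rho: float = 0.5) -> list[BehaviorSession]:
    """Per-animal freezing percentages for both tones (paired structure).

    Marginals are Beta distributions moment-matched to the preset
    (mean, SD); ``rho`` is the latent Gaussian-copula correlation between an
    animal's two tone responses.
    """
    n_animals = n_animals if n_animals is not None else preset.n_animals
    if n_animals < 1:
        raise InvalidParameterError("n_animals must be >= 1")
    sessions = []
    for i in range(n_animals):
        rng = _stream(seed, preset.label, _BEHAV, i)
        z_animal = rng.standard_normal()
        animal_id = f"{preset.label}-a{i:03d}"
        for j, tone in enumerate(TONES):
            mean, sd = preset.freezing[tone]
            z = rho * z_animal + np.sqrt(1.0 - rho ** 2) * rng.standard_normal()
            if sd == 0:
                f = mean
            else:
                mu, sigma = mean / 100.0, sd / 100.0
                if sigma ** 2 >= mu * (1.0 - mu):
                    raise InvalidParameterError(
                        f"freezing SD {sd} too large for mean {mean} "
                        "(no matching Beta distribution)")
                nu = mu * (1.0 - mu) / sigma ** 2 - 1.0
                f = 100.0 * sps.beta.ppf(sps.norm.cdf(z),
                                         mu * nu, (1.0 - mu) * nu)
            sessions.append(BehaviorSession(animal_id=animal_id,
                                            condition=preset.label,
                                            tone=tone,
                                            freezing_percent=float(f)))
    return sessions
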