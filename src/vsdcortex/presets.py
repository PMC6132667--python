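"""Condition presets: the generative parameter set for one experimental group.

Presets carry the published group summaries of the modeled de-/remyelination
study (means, between-slice SDs reconstructed as SEM*sqrt(n), sample sizes,
spike probabilities, freezing percentages) and are the recovery targets of
every downstream pipeline stage.  They ship with the package in
``data/presets.yaml``; see that file for provenance notes on interpolated
entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import InvalidParameterError
from .geometry import INFRA, SUPRA

TONES = ("2.5kHz", "10kHz")


@dataclass(frozen=True)
class ConditionPreset:
    """Generative parameters for one experimental group."""

    label: str
    n_slices: int
    n_latency_slices: int
    n_spike_slices: int
    n_animals: int
    vsd_amp: dict          # {layer: {intensity: (mean %, sd %)}}
    fp_amp: dict           # {layer: {intensity: (mean mV, sd mV)}}
    latency_ms: dict       # {layer: {distance: (mean ms, sd ms)}}
    spike_prob: dict       # {intensity: p}
    freezing: dict         # {tone: (mean %, sd %)}
    vsd_noise_pct: float = 0.03
    fp_noise_mv: float = 0.02

    def __post_init__(self):
        for layer in (SUPRA, INFRA):
            for table in (self.vsd_amp, self.fp_amp):
                for mean, sd in table[layer].values():
                    if sd < 0:
                        raise InvalidParameterError(
                            f"{self.label}: negative SD in amplitude table")
            for mean, sd in self.latency_ms[layer].values():
                if mean <= 0 or sd < 0:
                    raise InvalidParameterError(
                        f"{self.label}: latency mean must be > 0, SD >= 0")
        for p in self.spike_prob.values():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(
                    f"{self.label}: spike probability outside [0, 1]")
        for tone, (mean, sd) in self.freezing.items():
            if not 0.0 <= mean <= 100.0:
                raise InvalidParameterError(
                    f"{self.label}: freezing mean for {tone} outside [0, 100]")
            if sd < 0:
                raise InvalidParameterError(f"{self.label}: negative freezing SD")
        if self.vsd_noise_pct < 0 or self.fp_noise_mv < 0:
            raise InvalidParameterError(f"{self.label}: negative noise SD")

    def replace(self, **kwargs) -> "ConditionPreset":
        import dataclasses
        return dataclasses.replace(self, **kwargs)

    def with_zero_variability(self) -> "ConditionPreset":
        """Copy with all between-slice SDs and measurement noise set to zero.

        Useful for zero-noise identity checks: every pipeline measurement on
        such a cohort must equal its generative parameter.
        """
        def zero_sd(table):
            return {k: {kk: (vv[0], 0.0) for kk, vv in v.items()}
                    for k, v in table.items()}
        return self.replace(
            vsd_amp=zero_sd(self.vsd_amp),
            fp_amp=zero_sd(self.fp_amp),
            latency_ms=zero_sd(self.latency_ms),
            freezing={k: (v[0], 0.0) for k, v in self.freezing.items()},
            vsd_noise_pct=0.0, fp_noise_mv=0.0,
        )


_CACHE: dict[str, ConditionPreset] = {}


def _load_raw() -> dict:
    text = resources.files("vsdcortex").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def _parse(label: str, raw: dict) -> ConditionPreset:
    def pairs(table):
        return {k: {kk: (float(vv[0]), float(vv[1])) for kk, vv in v.items()}
                for k, v in table.items()}
    noise = raw.get("noise", {})
    return ConditionPreset(
        label=label,
        n_slices=int(raw["n_slices"]),
        n_latency_slices=int(raw["n_latency_slices"]),
        n_spike_slices=int(raw["n_spike_slices"]),
        n_animals=int(raw["n_animals"]),
        vsd_amp=pairs(raw["vsd_amp"]),
        fp_amp=pairs(raw["fp_amp"]),
        latency_ms=pairs(raw["latency_ms"]),
        spike_prob={int(k): float(v) for k, v in raw["spike_prob"].items()},
        freezing={str(k): (float(v[0]), float(v[1]))
                  for k, v in raw["freezing"].items()},
        vsd_noise_pct=float(noise.get("vsd_pct", 0.03)),
        fp_noise_mv=float(noise.get("fp_mv", 0.02)),
    )


def list_presets() -> list[str]:
    return sorted(_load_raw().keys())


def load_preset(label: str) -> ConditionPreset:
    if label not in _CACHE:
        raw = _load_raw()
        if label not in raw:
            raise InvalidParameterError(
                f"unknown preset {label!r}; available: {sorted(raw)}")
        _CACHE[label] = _parse(label, raw[label])
    return _CACHE[label]
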