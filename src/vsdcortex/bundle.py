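"""On-disk recording bundles.

A bundle is a directory holding a JSON metadata sidecar plus one CSV matrix
per VSD trial (rows = active sites in site_id order, columns = samples) and
one CSV per field-potential trace.  All reals are serialized with 17
significant digits so a write/read round trip is bit-exact for doubles.
The sidecar stores the geometry *parameters* (rings, pitch, deactivated
sites, band assignment), not the site table: geometry construction is
deterministic, so the reader rebuilds an identical lattice.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .errors import BundleFormatError
from .geometry import DiodeArrayGeometry, assign_layer_bands, build_hex_geometry
from .recordings import FieldPotentialTrace, StimulusSpec, VSDRecording

_SIDECAR = "metadata.json"
_FMT = "%.17g"


def _stim_to_dict(s: StimulusSpec) -> dict:
    return {"intensity_percent": s.intensity_percent,
            "electrode_distance": s.electrode_distance,
            "pulse_width_us": s.pulse_width_us,
            "position": s.position}


def _stim_from_dict(d: dict) -> StimulusSpec:
    return StimulusSpec(intensity_percent=int(d["intensity_percent"]),
                        electrode_distance=d["electrode_distance"],
                        pulse_width_us=float(d["pulse_width_us"]),
                        position=d.get("position"))


def write_bundle(geometry: DiodeArrayGeometry, recordings, traces, path) -> str:
    """Write a recording bundle; returns the bundle directory path."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    meta = {
        "format": "vsdcortex-bundle/1",
        "geometry": {
            "rings": geometry.rings,
            "spacing_mm": geometry.spacing,
            "deactivated": [list(s) for s in geometry.deactivated],
            "supra_fraction": geometry.supra_fraction,
            "cortical_axis": list(geometry.cortical_axis)
            if geometry.cortical_axis is not None else None,
            "n_active": geometry.n_active,
        },
        "recordings": [],
        "traces": [],
    }
    for i, rec in enumerate(recordings):
        fname = f"vsd_{i:04d}.csv"
        np.savetxt(os.path.join(path, fname), rec.intensities,
                   fmt=_FMT, delimiter=",")
        meta["recordings"].append({
            "file": fname,
            "slice_id": rec.slice_id,
            "condition": rec.condition,
            "trial_index": rec.trial_index,
            "stimulus_onset": rec.stimulus_onset,
            "sampling_interval_ms": rec.sampling_interval,
            "geometry_ref": rec.geometry_ref,
            "stimulation": _stim_to_dict(rec.stimulation),
        })
    for i, tr in enumerate(traces):
        fname = f"fp_{i:04d}.csv"
        np.savetxt(os.path.join(path, fname), tr.voltages,
                   fmt=_FMT, delimiter=",")
        meta["traces"].append({
            "file": fname,
            "slice_id": tr.slice_id,
            "condition": tr.condition,
            "layer": tr.layer,
            "stimulus_onset": tr.stimulus_onset,
            "sampling_interval_ms": tr.sampling_interval,
            "stimulation": _stim_to_dict(tr.stimulation),
        })
    with open(os.path.join(path, _SIDECAR), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_bundle(path):
    """Read a bundle; returns ``(geometry, recordings, traces)``.

    Raises :class:`BundleFormatError` (naming the offending field) on
    malformed sidecars or matrix/geometry mismatches.
    """
    path = os.fspath(path)
    sidecar = os.path.join(path, _SIDECAR)
    try:
        with open(sidecar) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        raise BundleFormatError(f"missing sidecar {_SIDECAR} in {path}")
    except json.JSONDecodeError as e:
        raise BundleFormatError(f"sidecar is not valid JSON: {e}")

    try:
        g = meta["geometry"]
        geometry = build_hex_geometry(int(g["rings"]), float(g["spacing_mm"]),
                                      [tuple(s) for s in g["deactivated"]])
        if g.get("supra_fraction") is not None:
            geometry = assign_layer_bands(geometry, float(g["supra_fraction"]),
                                          tuple(g["cortical_axis"]))
    except KeyError as e:
        raise BundleFormatError(f"sidecar geometry: missing field {e}")
    if geometry.n_active != int(g["n_active"]):
        raise BundleFormatError(
            f"geometry.n_active: sidecar claims {g['n_active']}, "
            f"rebuilt lattice has {geometry.n_active}")

    recordings = []
    for entry in meta.get("recordings", []):
        mat = np.loadtxt(os.path.join(path, entry["file"]),
                         delimiter=",", ndmin=2)
        if mat.shape[0] != geometry.n_active:
            raise BundleFormatError(
                f"{entry['file']}: intensities has {mat.shape[0]} rows, "
                f"geometry has {geometry.n_active} active sites")
        if not (mat > 0).all():
            raise BundleFormatError(
                f"{entry['file']}: intensities must be strictly positive")
        recordings.append(VSDRecording(
            intensities=mat,
            stimulus_onset=int(entry["stimulus_onset"]),
            stimulation=_stim_from_dict(entry["stimulation"]),
            slice_id=entry["slice_id"],
            condition=entry["condition"],
            trial_index=int(entry["trial_index"]),
            sampling_interval=float(entry["sampling_interval_ms"]),
            geometry_ref=entry.get("geometry_ref", "default-464"),
        ))
    traces = []
    for entry in meta.get("traces", []):
        v = np.loadtxt(os.path.join(path, entry["file"]), delimiter=",")
        traces.append(FieldPotentialTrace(
            voltages=np.atleast_1d(v),
            stimulus_onset=int(entry["stimulus_onset"]),
            layer=entry["layer"],
            stimulation=_stim_from_dict(entry["stimulation"]),
            slice_id=entry["slice_id"],
            condition=entry["condition"],
            sampling_interval=float(entry["sampling_interval_ms"]),
        ))
    return geometry, recordings, traces
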