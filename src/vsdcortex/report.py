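"""End-to-end experiment orchestration: simulate -> analyze -> stats.

``run_experiment`` generates one synthetic cohort per configured group,
runs the VSD and FP pipelines and the behavior scoring, compares groups
with the ANOVA + post-hoc layer, and writes one tidy CSV per table plus a
JSON index and a machine-readable recovery table (generative parameter vs
pipeline estimate, in units of the generative SEM).  Under a fixed seed two
runs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .behavior import discrimination_summary, sessions_frame
from .errors import ConfigurationError
from .fp import io_curve, slice_spike_scores, spike_fraction
from .geometry import INFRA, SUPRA, default_array
from .measure import measure_fp_cohort, measure_vsd_cohort
from .presets import TONES, load_preset
from .simulate import generate_behavior_cohort, generate_cohort
from .stats import anova_oneway, newman_keuls
from .vsd import fractional_fluorescence, average_trials, layer_time_heatmap

log = logging.getLogger("vsdcortex")

DEFAULT_CONFIG = {
    "groups": ["control", "cuprizone", "remy7", "remy25"],
    "behavior_groups": ["control", "cuprizone", "remy7_dmf", "remy25_dmf"],
    "intensities": [50],
    "electrode_distance": "short",
    "n_trials": 3,
    "seed": 0,
    "n_depth_bins": 6,
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: dict | None = None, out_dir: str = "report") -> dict:
    """Run the full synthetic experiment; returns the JSON index as a dict."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    for label in cfg["groups"] + cfg["behavior_groups"]:
        load_preset(label)   # raises early on unknown presets
    if cfg.get("n_slices", None) is not None and int(cfg["n_slices"]) < 1:
        raise ConfigurationError("n_slices must be >= 1 when given")

    os.makedirs(out_dir, exist_ok=True)
    geometry = default_array()
    vsd_tables, fp_tables, spike_rows, io_rows, recovery = [], [], [], [], []
    heatmap_files = {}

    for label in cfg["groups"]:
        preset = load_preset(label)
        n_slices = int(cfg.get("n_slices") or preset.n_slices)
        log.info("simulating %s (n=%d slices)", label, n_slices)
        _, recordings, traces = generate_cohort(
            preset, geometry, n_slices=n_slices,
            intensities=cfg["intensities"], seed=seed,
            electrode_distance=cfg["electrode_distance"],
            n_trials=int(cfg["n_trials"]))
        vsd_df = measure_vsd_cohort(geometry, recordings)
        fp_df = measure_fp_cohort(traces)
        vsd_tables.append(vsd_df)
        fp_tables.append(fp_df)

        frac = spike_fraction(slice_spike_scores(traces))
        for intensity, pct in frac.items():
            spike_rows.append({"condition": label,
                               "intensity_percent": intensity,
                               "spike_percent": pct})
        for layer in (SUPRA, INFRA):
            sub = fp_df[fp_df["layer"] == layer]
            for pt in io_curve(sub, label, layer).points:
                io_rows.append({"condition": label, "layer": layer,
                                "intensity_percent": pt[0],
                                "mean_mv": pt[1], "sem_mv": pt[2]})

        # laminar heatmap from the averaged dI/I of each slice
        signals = []
        by_slice: dict = {}
        for rec in recordings:
            by_slice.setdefault(rec.slice_id, []).append(rec)
        for sid in sorted(by_slice):
            signals.append(average_trials(
                [fractional_fluorescence(r) for r in by_slice[sid]]))
        hm = layer_time_heatmap(signals, geometry,
                                n_depth_bins=int(cfg["n_depth_bins"]))
        fname = os.path.join(out_dir, f"heatmap_{label}.csv")
        np.savetxt(fname, hm, fmt="%.9g", delimiter=",")
        heatmap_files[label] = os.path.basename(fname)

        # recovery entries: generative mean vs pipeline estimate
        for intensity in cfg["intensities"]:
            for layer in (SUPRA, INFRA):
                gen_m, gen_sd = preset.vsd_amp[layer][intensity]
                est = vsd_df[(vsd_df["layer"] == layer)
                             & (vsd_df["intensity_percent"] == intensity)
                             ]["amplitude_pct"].mean()
                sem = gen_sd / np.sqrt(n_slices) if gen_sd > 0 else float("nan")
                recovery.append({
                    "quantity": "vsd_amplitude_pct", "condition": label,
                    "layer": layer, "intensity_percent": intensity,
                    "generative": gen_m, "recovered": float(est),
                    "generative_sem": sem,
                    "z": float((est - gen_m) / sem) if sem and np.isfinite(sem)
                    else float("nan"),
                })
                gen_m, gen_sd = preset.fp_amp[layer][intensity]
                est = fp_df[(fp_df["layer"] == layer)
                            & (fp_df["intensity_percent"] == intensity)
                            ]["amplitude_mv"].mean()
                sem = gen_sd / np.sqrt(n_slices) if gen_sd > 0 else float("nan")
                recovery.append({
                    "quantity": "fp_amplitude_mv", "condition": label,
                    "layer": layer, "intensity_percent": intensity,
                    "generative": gen_m, "recovered": float(est),
                    "generative_sem": sem,
                    "z": float((est - gen_m) / sem) if sem and np.isfinite(sem)
                    else float("nan"),
                })

    vsd_all = pd.concat(vsd_tables, ignore_index=True)
    fp_all = pd.concat(fp_tables, ignore_index=True)
    vsd_all.to_csv(os.path.join(out_dir, "vsd_measurements.csv"), index=False)
    fp_all.to_csv(os.path.join(out_dir, "fp_measurements.csv"), index=False)
    pd.DataFrame(spike_rows).to_csv(
        os.path.join(out_dir, "spike_fractions.csv"), index=False)
    pd.DataFrame(io_rows).to_csv(
        os.path.join(out_dir, "io_curves.csv"), index=False)

    # group comparisons: one-way ANOVA + Newman-Keuls per layer x intensity
    anova_rows, posthoc_rows = [], []
    for measure, table, col in (("vsd_amplitude_pct", vsd_all, "amplitude_pct"),
                                ("fp_amplitude_mv", fp_all, "amplitude_mv")):
        for (layer, intensity), sub in table.groupby(
                ["layer", "intensity_percent"]):
            groups = [g[col].to_numpy()
                      for _, g in sub.groupby("condition", sort=True)]
            labels = sorted(sub["condition"].unique())
            if len(groups) < 2:
                continue
            res = anova_oneway(groups)
            anova_rows.append({
                "measure": measure, "layer": layer,
                "intensity_percent": intensity, "effect": res.effect,
                "df_num": res.df_num, "df_den": res.df_den,
                "F": res.F, "p": res.p,
                "ss_effect": res.ss_effect, "ss_error": res.ss_error,
            })
            if res.flagged_degenerate:
                continue
            nk = newman_keuls([g.mean() for g in groups],
                              mse=res.ss_error / res.df_den,
                              df_error=res.df_den,
                              n_per_group=[g.size for g in groups],
                              labels=labels)
            for a, b, q, crit, sig in nk.pairs:
                posthoc_rows.append({
                    "measure": measure, "layer": layer,
                    "intensity_percent": intensity, "method": nk.method,
                    "group_a": a, "group_b": b, "q": q,
                    "q_critical": crit, "significant": sig,
                })
    pd.DataFrame(anova_rows).to_csv(
        os.path.join(out_dir, "anova.csv"), index=False)
    pd.DataFrame(posthoc_rows).to_csv(
        os.path.join(out_dir, "posthoc.csv"), index=False)

    # behavior
    behavior_rows = []
    for label in cfg["behavior_groups"]:
        preset = load_preset(label)
        sessions = generate_behavior_cohort(preset, seed=seed)
        summary = discrimination_summary(sessions_frame(sessions), label)
        for tone in TONES:
            mean, sem = summary.mean_freezing[tone]
            gen_m, gen_sd = preset.freezing[tone]
            gen_sem = gen_sd / np.sqrt(summary.n_animals) if gen_sd > 0 else float("nan")
            behavior_rows.append({
                "condition": label, "tone": tone, "n_animals": summary.n_animals,
                "mean_freezing_pct": mean, "sem_pct": sem,
                "paired_delta_pct": summary.paired_delta,
                "contrast_F": summary.F, "contrast_p": summary.p,
                "discriminates": summary.discriminates,
            })
            recovery.append({
                "quantity": "freezing_pct", "condition": label, "tone": tone,
                "generative": gen_m, "recovered": mean,
                "generative_sem": gen_sem,
                "z": float((mean - gen_m) / gen_sem)
                if gen_sem and np.isfinite(gen_sem) else float("nan"),
            })
    pd.DataFrame(behavior_rows).to_csv(
        os.path.join(out_dir, "behavior_summary.csv"), index=False)

    with open(os.path.join(out_dir, "recovery.json"), "w") as fh:
        json.dump(recovery, fh, indent=1, sort_keys=True)

    index = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "tables": sorted(f for f in os.listdir(out_dir) if f.endswith(".csv")),
        "heatmaps": heatmap_files,
    }
    with open(os.path.join(out_dir, "index.json"), "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)
    return index
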