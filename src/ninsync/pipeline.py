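"""End-to-end session pipeline.

``run_pipeline`` orchestrates: simulate (or load) a session, detect
calcium-event onsets, find synchronous patterns and build the SP graph,
classify SP-triggered acceleration and parse rearing/turn epochs, run the
stimulus-response analyses if a stimulation log is present, and write all
artifacts plus a machine-readable JSON report. Given the same config
(including seed) the report is byte-identical across runs.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import events as ev
from . import graph as gr
from . import io as nio
from . import stim as st
from . import sync as sy
from .synth import SynthConfig, simulate_session

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "simulate": True,
    "seed": 0,
    "out_dir": None,
    "paths": {"traces": None, "regions": None, "accel": None, "stim": None},
    "synth": {},  # overrides for SynthConfig fields
    "onset": {
        "rise_tau_s": 0.03,
        "t_half_s": 0.3,
        "threshold_sigma": 3.0,
        "refractory_s": 0.2,
    },
    "sp": {"h_s": 0.1, "dt_s": 0.01, "min_co": 5},
    "behavior": {
        "win_s": 2.0,
        "around_s": 0.15,
        "baseline_frac": 0.25,
        "rearing_theta_on_g": 0.1,
        "rearing_theta_off_g": 0.05,
        "turn_theta_g": 0.1,
        "n_random_triggers": 100,
    },
    "stim_response": {"pre_s": 2.0, "post_s": 4.0, "alpha": 0.05},
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    def merge(user: dict, default: dict, prefix: str) -> dict:
        out = copy.deepcopy(default)
        for k, v in user.items():
            if k == "synth":
                bad = set(v) - set(SynthConfig.__dataclass_fields__)
                if bad:
                    raise ValueError(f"unknown synth keys: {sorted(bad)}")
                out[k] = copy.deepcopy(v)
                continue
            if k not in default:
                raise ValueError(f"unknown config key: {prefix}{k}")
            if isinstance(default[k], dict) and isinstance(v, dict):
                out[k] = merge(v, default[k], f"{prefix}{k}.")
            else:
                out[k] = v
        return out

    cfg = merge(config, DEFAULT_CONFIG, "")
    if not cfg["simulate"]:
        for need in ("traces", "accel"):
            if not cfg["paths"][need]:
                raise ValueError(
                    f"paths.{need} is required when simulate is false"
                )
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _stage_inputs(cfg: dict):
    if cfg["simulate"]:
        synth_cfg = SynthConfig(**{**cfg["synth"], "seed": cfg["seed"]})
        traces, accel, stim, truth = simulate_session(synth_cfg)
        return traces, accel, stim, truth
    paths = cfg["paths"]
    with open(paths["regions"]) as fh:
        region_map = yaml.safe_load(fh)
    traces = nio.read_trace_table(paths["traces"], region_map)
    accel = nio.read_accel_table(paths["accel"])
    stim = nio.read_stim_table(paths["stim"]) if paths["stim"] else None
    return traces, accel, stim, None


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run the full analysis and return (and optionally write) the report.

    If ``out_dir`` (or config out_dir) is given, the artifacts — events,
    kernel sum, sync events, SP edge list, behavior epochs, responder and
    modulation tables, GraphML, report JSON — are written there.
    """
    cfg = validate_config(config)
    out = Path(out_dir or cfg["out_dir"]) if (out_dir or cfg["out_dir"]) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    traces, accel, stim, truth = _stage_inputs(cfg)
    duration = traces.duration_s

    # --- event inference ----------------------------------------------------
    params = ev.OnsetParams(**cfg["onset"])
    trains = ev.detect_onsets_matrix(traces, params)
    rates = {tr.cell_id: ev.event_rate(tr, duration) for tr in trains}
    region_rates: dict[str, float] = {}
    for reg in sorted(set(traces.region)):
        rs = [rates[tr.cell_id] for tr in trains if tr.region == reg]
        region_rates[reg] = float(np.mean(rs)) if rs else 0.0

    # --- SP detection -------------------------------------------------------
    sp_cfg = cfg["sp"]
    series = sy.kernel_sum(
        trains, h_s=sp_cfg["h_s"], dt_s=sp_cfg["dt_s"], duration_s=duration
    )
    sync_events = sy.detect_sync_events(series, trains)
    graph = sy.build_sp_graph(sync_events, trains, min_co=sp_cfg["min_co"])
    scope = sy.classify_sp_scope(graph)
    layout = gr.degree_layout(graph)

    # --- behavior -----------------------------------------------------------
    b_cfg = cfg["behavior"]
    comp = bh.compound_accel(accel)
    sp_times = np.array([e.t0 for e in sync_events])
    trig_classes, trig_fracs, n_edge_dropped = bh.classify_sp_triggers(
        comp, sp_times, win_s=b_cfg["win_s"], around_s=b_cfg["around_s"],
        baseline_frac=b_cfg["baseline_frac"],
    )
    if sp_times.size:
        frac_rand, frac_sp, p_null = bh.random_trigger_null(
            comp, b_cfg["n_random_triggers"], sp_times,
            seed=np.random.default_rng(cfg["seed"] + 1),
            win_s=b_cfg["win_s"], around_s=b_cfg["around_s"],
            baseline_frac=b_cfg["baseline_frac"],
        )
    else:
        frac_rand = frac_sp = 0.0
        p_null = 1.0
    rearing = bh.detect_rearings(
        accel, theta_on_g=b_cfg["rearing_theta_on_g"],
        theta_off_g=b_cfg["rearing_theta_off_g"],
    )
    turns = bh.detect_turns(accel, theta_g=b_cfg["turn_theta_g"])

    # --- stimulus response --------------------------------------------------
    stim_report = None
    if stim is not None and stim.n_stimuli >= 2:
        s_cfg = cfg["stim_response"]
        tensor = st.build_trials(
            traces, stim, pre_s=s_cfg["pre_s"], post_s=s_cfg["post_s"]
        )
        resp_calls, resp_frac = st.classify_responders(tensor)
        mod_calls, mod_fracs, cluster_rates = st.classify_modulation(
            tensor, alpha=s_cfg["alpha"], trains=trains, stim=stim
        )
        onsets = [c.onset_s for c in resp_calls if c.onset_s is not None]
        stim_report = {
            "n_trials": tensor.n_trials,
            "n_dropped_trials": tensor.n_dropped,
            "responder_fraction": resp_frac,
            "median_onset_s": float(np.median(onsets)) if onsets else None,
            "modulation_fractions": mod_fracs,
            "cluster_event_rates_hz": {
                k: (None if np.isnan(v) else v) for k, v in cluster_rates.items()
            },
        }

    # --- artifacts ----------------------------------------------------------
    if out:
        ev_rows = [
            (tr.cell_id, tr.region, t, a)
            for tr in trains
            for t, a in zip(tr.onsets, tr.amplitudes)
        ]
        pd.DataFrame(
            ev_rows, columns=["cell_id", "region", "onset_s", "amplitude"]
        ).to_csv(out / "events.csv", index=False, float_format="%.9g")
        manifest.append("events.csv")
        pd.DataFrame({"t": series.grid_ts, "S": series.S}).to_csv(
            out / "kernel_sum.csv", index=False, float_format="%.9g"
        )
        manifest.append("kernel_sum.csv")
        pd.DataFrame(
            [(e.t0, e.t1, len(e.participants)) for e in sync_events],
            columns=["t0", "t1", "n_participants"],
        ).to_csv(out / "sync_events.csv", index=False, float_format="%.9g")
        manifest.append("sync_events.csv")
        gr.export_graph(graph, out / "sp_graph.csv", fmt="csv")
        manifest += ["sp_graph.csv", "sp_graph.csv.nodes.csv"]
        gr.export_graph(graph, out / "sp_graph.graphml", fmt="graphml")
        manifest.append("sp_graph.graphml")
        epochs = rearing.epochs + turns
        pd.DataFrame(
            [(e.kind, e.t_start, e.t_end) for e in epochs],
            columns=["kind", "t_start", "t_end"],
        ).to_csv(out / "behavior_epochs.csv", index=False, float_format="%.9g")
        manifest.append("behavior_epochs.csv")
        pd.DataFrame(
            [(r.sp_time, r.category) for r in trig_classes],
            columns=["sp_time", "category"],
        ).to_csv(out / "sp_trigger_classes.csv", index=False, float_format="%.9g")
        manifest.append("sp_trigger_classes.csv")

    report = {
        "config": cfg,
        "seed": cfg["seed"],
        "n_cells": traces.n_cells,
        "duration_s": duration,
        "events": {
            "n_events_total": int(sum(tr.n_events for tr in trains)),
            "mean_rate_hz_by_region": region_rates,
        },
        "sp": {
            "n_sync_events": len(sync_events),
            "n_edges": graph.number_of_edges(),
            "n_sp_edges": int(
                sum(1 for *_, d in graph.edges(data=True) if d["sp_flag"])
            ),
            "n_within_sp": scope.n_within,
            "n_across_sp": scope.n_across,
            "participation_within": scope.participation_within,
            "participation_across": scope.participation_across,
        },
        "behavior": {
            "trigger_fractions": trig_fracs,
            "n_triggers_classified": len(trig_classes),
            "n_triggers_dropped_edge": n_edge_dropped,
            "random_trigger_null": {
                "frac_random": frac_rand,
                "frac_sp": frac_sp,
                "p_value": p_null,
            },
            "rearing_rate_per_min": rearing.rate_per_min,
            "rearing_mean_duration_s": rearing.mean_duration_s,
            "n_rearings": len(rearing.epochs),
            "n_turns": len(turns),
        },
        "stim_response": stim_report,
        "layout_order": layout.order,
        "manifest": sorted(manifest),
    }
    if truth is not None:
        report["ground_truth_summary"] = {
            "n_planted_sp": int(truth.sp_times.size),
            "n_planted_pairs": len(truth.ensemble_pairs),
            "n_planted_rearings": len(truth.rearing_intervals),
            "n_planted_bouts": len(truth.movement_bouts),
        }
    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        report["manifest"].append("report.json")
    return report
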