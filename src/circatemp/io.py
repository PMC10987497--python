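"""Delimited-text I/O for every domain table, plus config and manifests.

Conventions: explicit headers, ZT always in hours as floats, epochs
0-based, all intervals half-open. Floats are written with ``%.10g`` so
reader/writer pairs round-trip to 1e-9 relative precision; integers
round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calcium import DeltaFTrace, FluorescenceTrace, TemperatureProtocol, TemperatureResponse
from .diurnal import CircadianCurve, DiurnalGroup, FlySeries
from .sleep import ActivityRecord
from .synth import (
    ActivityParams,
    CalciumParams,
    GaussianPeak,
    PiecewiseZT,
    SynthConfig,
    TempEffect,
)

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Activity tables (long format)
# ---------------------------------------------------------------------------

def write_activity(records: list[ActivityRecord], path: str | Path) -> None:
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": r.fly_id,
                    "temp_condition": r.temp_condition,
                    "day_index": r.day_index,
                    "epoch_index": np.arange(r.counts.size),
                    "count": r.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_activity(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    records = []
    for (fly, cond, day), sub in df.groupby(
        ["fly_id", "temp_condition", "day_index"], sort=True
    ):
        sub = sub.sort_values("epoch_index")
        records.append(
            ActivityRecord(
                fly_id=str(fly),
                temp_condition=str(cond),
                counts=sub["count"].to_numpy(),
                day_index=int(day),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Fluorescence trace tables (long format)
# ---------------------------------------------------------------------------

def write_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "roi_id": t.roi_id,
                    "neuron_class": t.neuron_class,
                    "channel": t.channel,
                    "zt": t.zt,
                    "time_s": t.times,
                    "value": t.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    traces = []
    for (roi, cls, chan, zt), sub in df.groupby(
        ["roi_id", "neuron_class", "channel", "zt"], sort=True
    ):
        sub = sub.sort_values("time_s")
        traces.append(
            FluorescenceTrace(
                roi_id=str(roi),
                neuron_class=str(cls),
                channel=str(chan),
                times=sub["time_s"].to_numpy(),
                values=sub["value"].to_numpy(),
                zt=float(zt),
            )
        )
    return traces


def write_dff(dffs: list[DeltaFTrace], path: str | Path) -> None:
    frames = []
    for d in dffs:
        frames.append(
            pd.DataFrame(
                {
                    "roi_id": d.roi_id,
                    "neuron_class": d.neuron_class,
                    "zt": d.zt,
                    "f0": d.f0,
                    "baseline_start_s": d.baseline_window[0],
                    "baseline_end_s": d.baseline_window[1],
                    "time_s": d.times,
                    "dff_percent": d.dff,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_dff(path: str | Path) -> list[DeltaFTrace]:
    df = pd.read_csv(path)
    out = []
    for (roi, cls, zt, f0, b0, b1), sub in df.groupby(
        ["roi_id", "neuron_class", "zt", "f0", "baseline_start_s", "baseline_end_s"],
        sort=True,
    ):
        sub = sub.sort_values("time_s")
        out.append(
            DeltaFTrace(
                roi_id=str(roi),
                times=sub["time_s"].to_numpy(),
                dff=sub["dff_percent"].to_numpy(),
                f0=float(f0),
                baseline_window=(float(b0), float(b1)),
                neuron_class=str(cls),
                zt=float(zt),
            )
        )
    return out


def responses_to_frame(responses: list[TemperatureResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in responses],
            "neuron_class": [r.neuron_class for r in responses],
            "zt": [r.zt for r in responses],
            "delta_t_c": [r.delta_t_c for r in responses],
            "pre_mean": [r.pre_mean for r in responses],
            "post_mean": [r.post_mean for r in responses],
            "fold_change": [r.fold_change for r in responses],
            "max_dff": [r.max_dff for r in responses],
            "response_class": [r.response_class for r in responses],
            "baseline_sd": [r.baseline_sd for r in responses],
        }
    )


# ---------------------------------------------------------------------------
# Diurnal group tables & curves
# ---------------------------------------------------------------------------

def write_diurnal_groups(groups: list[DiurnalGroup], path: str | Path) -> None:
    frames = []
    for g in groups:
        for fly in g.flies:
            frames.append(
                pd.DataFrame(
                    {
                        "group_shift_h": g.shift_h,
                        "fly_id": fly.fly_id,
                        "local_time_h": fly.local_time_h,
                        "gcamp": fly.gcamp,
                        "tdtom": fly.tdtom,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_diurnal_groups(path: str | Path) -> list[DiurnalGroup]:
    df = pd.read_csv(path)
    groups = []
    for shift, gsub in df.groupby("group_shift_h", sort=True):
        flies = []
        for fly, fsub in gsub.groupby("fly_id", sort=True):
            fsub = fsub.sort_values("local_time_h")
            flies.append(
                FlySeries(
                    fly_id=str(fly),
                    local_time_h=fsub["local_time_h"].to_numpy(),
                    gcamp=fsub["gcamp"].to_numpy(),
                    tdtom=fsub["tdtom"].to_numpy(),
                )
            )
        groups.append(DiurnalGroup(shift_h=float(shift), flies=flies))
    return groups


def write_curve(curve: CircadianCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_curve(path: str | Path) -> CircadianCurve:
    df = pd.read_csv(path)
    return CircadianCurve(
        bin_centers=df["zt"].to_numpy(),
        mean=df["mean"].to_numpy(),
        sem=df["sem"].to_numpy(),
        n=df["n"].to_numpy().astype(int),
    )


# ---------------------------------------------------------------------------
# Temperature protocols (YAML/JSON)
# ---------------------------------------------------------------------------

def write_protocol(protocol: TemperatureProtocol, path: str | Path) -> None:
    doc = {
        "baseline_c": protocol.baseline_c,
        "recording_span_s": protocol.recording_span_s,
        "steps": [
            {"onset_s": s[0], "target_c": s[1], "ramp_s": s[2]}
            for s in protocol.steps
        ],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))


def read_protocol(path: str | Path) -> TemperatureProtocol:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return TemperatureProtocol(
        baseline_c=float(doc["baseline_c"]),
        steps=[
            (float(s["onset_s"]), float(s["target_c"]), float(s["ramp_s"]))
            for s in doc["steps"]
        ],
        recording_span_s=float(doc["recording_span_s"]),
    )


# ---------------------------------------------------------------------------
# SynthConfig (YAML/JSON)
# ---------------------------------------------------------------------------

def config_to_dict(config: SynthConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    # tuple-keyed coupling map -> "PRE->POST" strings for serializability
    d["calcium"]["coupling"] = {
        f"{pre}->{post}": w for (pre, post), w in config.calcium.coupling.items()
    }
    return d


def config_from_dict(d: dict[str, Any]) -> SynthConfig:
    d = json.loads(json.dumps(d))  # deep copy, normalize tuples to lists

    def peak(p: dict) -> GaussianPeak:
        return GaussianPeak(**p)

    def pw(p: dict) -> PiecewiseZT:
        return PiecewiseZT(edges=tuple(p["edges"]), values=tuple(p["values"]))

    act = d.get("activity", {})
    activity = ActivityParams(
        baseline_rate=act.get("baseline_rate", 1.0),
        morning=peak(act["morning"]) if "morning" in act else ActivityParams().morning,
        evening=peak(act["evening"]) if "evening" in act else ActivityParams().evening,
        wake_prob=pw(act["wake_prob"]) if "wake_prob" in act else ActivityParams().wake_prob,
        switch_rate=act.get("switch_rate", 0.01),
        siesta_window=tuple(act.get("siesta_window", (4.0, 8.0))),
    )
    cal = d.get("calcium", {})
    coupling = {}
    for key, w in cal.get("coupling", {"DN1a->LNd": -0.6, "DN1a->DN3": -0.8}).items():
        pre, post = key.split("->")
        coupling[(pre, post)] = float(w)
    defaults = CalciumParams()
    calcium = CalciumParams(
        baseline_mid=cal.get("baseline_mid", defaults.baseline_mid),
        baseline_amp=cal.get("baseline_amp", defaults.baseline_amp),
        gating=pw(cal["gating"]) if "gating" in cal else defaults.gating,
        gains=cal.get("gains", dict(defaults.gains)),
        coupling=coupling,
        sat_cool_c=cal.get("sat_cool_c", defaults.sat_cool_c),
        sat_heat_c=cal.get("sat_heat_c", defaults.sat_heat_c),
        tau_sensor_s=cal.get("tau_sensor_s", defaults.tau_sensor_s),
        kappa=cal.get("kappa", defaults.kappa),
        f0_gcamp=cal.get("f0_gcamp", defaults.f0_gcamp),
        f0_tdtom=cal.get("f0_tdtom", defaults.f0_tdtom),
        noise_sd=cal.get("noise_sd", defaults.noise_sd),
        bleach_tau_s=cal.get("bleach_tau_s", defaults.bleach_tau_s),
        sample_hz=cal.get("sample_hz", defaults.sample_hz),
        diurnal_noise_sd=cal.get("diurnal_noise_sd", defaults.diurnal_noise_sd),
    )
    effects = {
        name: TempEffect(**eff) for name, eff in d.get("temp_effects", {}).items()
    }
    cfg = SynthConfig(
        master_seed=d.get("master_seed", 0),
        n_flies=d.get("n_flies", 8),
        n_days=d.get("n_days", 1),
        lights_on_zt=d.get("lights_on_zt", 0.0),
        lights_off_zt=d.get("lights_off_zt", 12.0),
        activity=activity,
        calcium=calcium,
        ablate_dn1a=d.get("ablate_dn1a", False),
    )
    if effects:
        cfg = dataclasses.replace(cfg, temp_effects=effects)
    return cfg


def write_config(config: SynthConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def read_config(path: str | Path) -> SynthConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(d)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    seed: int,
    parameters: dict[str, Any],
    outputs: list[str | Path],
    name: str = "manifest.json",
) -> Path:
    """Write a run manifest: seed + parameters + output checksums.

    The manifest contains everything needed to reproduce the outputs
    bit-for-bit (no timestamps, no environment state).
    """
    out_dir = Path(out_dir)
    doc = {
        "seed": seed,
        "parameters": parameters,
        "outputs": {
            str(Path(p).relative_to(out_dir)): sha256_of(p) for p in outputs
        },
    }
    path = out_dir / name
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
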