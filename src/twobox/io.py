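"""Session-bundle and result-file I/O.

A session bundle is one directory per trial (``trial1_baseline1`` ...)
holding ``position.csv`` (t, x, y in the room frame), ``spikes_<cell>.csv``,
``waveforms.h5`` and ``trial.json`` metadata, plus session-level
``session.json`` and ``ground_truth.json``.  Floats are written with a fixed
format so identical seeds reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import BoxGeometry
from .synth import (
    EnsembleConfig,
    GroundTruthCell,
    SessionBundle,
    SpikeTrain,
    Trajectory,
    Trial,
)

FLOAT_FMT = "%.6f"


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_session(bundle: SessionBundle, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    geo = bundle.geometry
    _dump_json(
        {
            "session_id": bundle.session_id,
            "geometry": {
                "compartment_width": geo.compartment_width,
                "compartment_height": geo.compartment_height,
                "door_width": geo.door_width,
                "odor_assignment": {str(k): v for k, v in geo.odor_assignment.items()},
            },
            "config": {
                **dataclasses.asdict(bundle.config),
                "odor_switch_trials": sorted(bundle.config.odor_switch_trials),
            },
        },
        path / "session.json",
    )
    _dump_json(
        {
            "cells": [
                {
                    **dataclasses.asdict(c),
                    "field_centers": {
                        str(k): [float(v[0]), float(v[1])]
                        for k, v in c.field_centers.items()
                    },
                }
                for c in bundle.cells
            ],
            "odor_switch_trials": sorted(bundle.config.odor_switch_trials),
        },
        path / "ground_truth.json",
    )
    for trial in bundle.trials:
        tdir = path / f"trial{trial.index}_{trial.name}"
        tdir.mkdir(exist_ok=True)
        pd.DataFrame({"t": trial.traj.t, "x": trial.traj.x, "y": trial.traj.y}).to_csv(
            tdir / "position.csv", index=False, float_format=FLOAT_FMT
        )
        _dump_json(
            {
                "index": trial.index,
                "name": trial.name,
                "door_open": trial.door_open,
                "rotation_deg": trial.rotation_deg,
                "single_compartment": trial.single_compartment,
                "odor_switched": trial.odor_switched,
                "duration": trial.traj.duration,
                "fs": trial.traj.fs,
            },
            tdir / "trial.json",
        )
        for cid, st in trial.spikes.items():
            pd.DataFrame({"t": st.spike_times}).to_csv(
                tdir / f"spikes_{cid}.csv", index=False, float_format=FLOAT_FMT
            )
        with h5py.File(tdir / "waveforms.h5", "w") as fh:
            fh.attrs["sampling_rate"] = 48000.0
            for cid, wf in trial.waveforms.items():
                fh.create_dataset(cid, data=wf)
    return path


def read_session(path) -> SessionBundle:
    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    g = meta["geometry"]
    geometry = BoxGeometry(
        compartment_width=g["compartment_width"],
        compartment_height=g["compartment_height"],
        door_width=g["door_width"],
        odor_assignment={int(k): v for k, v in g["odor_assignment"].items()},
    )
    cfg = dict(meta["config"])
    cfg["odor_switch_trials"] = frozenset(cfg.get("odor_switch_trials", ()))
    for key in ("category_proportions",):
        if key in cfg and cfg[key] is not None:
            cfg[key] = dict(cfg[key])
    for key in ("peak_rate_range", "sigma_range", "baseline_range",
                "distractor_rate_range"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    config = EnsembleConfig(**cfg)
    truth = json.loads((path / "ground_truth.json").read_text())
    cells = [
        GroundTruthCell(
            cell_id=c["cell_id"],
            category=c["category"],
            field_centers={
                int(k): np.asarray(v) for k, v in c["field_centers"].items()
            },
            field_width=c["field_width"],
            peak_rate=c["peak_rate"],
            baseline_rate=c["baseline_rate"],
            tetrode=c.get("tetrode", 0),
        )
        for c in truth["cells"]
    ]
    trials = []
    for tdir in sorted(path.glob("trial*_*")):
        tmeta = json.loads((tdir / "trial.json").read_text())
        pos = pd.read_csv(tdir / "position.csv")
        traj = Trajectory(
            t=pos["t"].to_numpy(),
            x=pos["x"].to_numpy(),
            y=pos["y"].to_numpy(),
            duration=tmeta["duration"],
            fs=tmeta["fs"],
        )
        waveforms = {}
        wf_path = tdir / "waveforms.h5"
        if wf_path.exists():
            with h5py.File(wf_path, "r") as fh:
                waveforms = {cid: fh[cid][()] for cid in fh}
        spikes = {}
        for sp in sorted(tdir.glob("spikes_*.csv")):
            cid = sp.stem[len("spikes_"):]
            st = pd.read_csv(sp)["t"].to_numpy() if sp.stat().st_size > 4 else np.empty(0)
            spikes[cid] = SpikeTrain(
                cell_id=cid, spike_times=np.atleast_1d(st).astype(float),
                waveform=waveforms.get(cid),
            )
        trials.append(
            Trial(
                index=tmeta["index"],
                name=tmeta["name"],
                door_open=tmeta["door_open"],
                rotation_deg=tmeta["rotation_deg"],
                single_compartment=tmeta["single_compartment"],
                odor_switched=tmeta.get("odor_switched", False),
                traj=traj,
                spikes=spikes,
                waveforms=waveforms,
            )
        )
    trials.sort(key=lambda t: t.index)
    return SessionBundle(
        session_id=meta["session_id"],
        geometry=geometry,
        config=config,
        cells=cells,
        trials=trials,
    )


def write_ratemaps_h5(maps: dict, path, params: dict | None = None) -> None:
    """``maps``: {(trial_name, cell_id): RateMap} -> one HDF5 file; the map
    parameters are echoed into ``ratemap_params.json`` next to it."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for (trial, cid), m in maps.items():
            grp = fh.require_group(trial).require_group(cid)
            grp.create_dataset("rate", data=m.rate)
            grp.create_dataset("dwell", data=m.dwell)
            grp.create_dataset("mask", data=m.mask.astype(np.uint8))
            grp.attrs["bin_size"] = m.bin_size
            grp.attrs["extent"] = m.extent
    if params is not None:
        _dump_json(params, path.with_name("ratemap_params.json"))


def write_null_h5(nulls: dict, path) -> None:
    with h5py.File(path, "w") as fh:
        for kind, nd in nulls.items():
            grp = fh.require_group(kind)
            grp.create_dataset("values", data=nd.values)
            grp.attrs["threshold"] = nd.threshold
            grp.attrs["percentile"] = nd.percentile
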