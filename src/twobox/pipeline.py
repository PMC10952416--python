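"""End-to-end 2-box analysis pipeline.

Chains: speed filter -> rate maps -> unit QC / field detection / shuffle
admission -> (multi-session) duplicate-cell removal -> null thresholds ->
ensemble-orientation detection and correction -> repeat/remap/rotate
classification with cue-control and stability gates -> single-compartment
odor-retrieval comparison -> behavioral preference index, and writes the
tabular outputs.  No cell is silently dropped: every cell appears in the
admission table with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tbio
from .behavior import preference_index
from .config import PipelineConfig
from .geometry import rotated_extent
from .ratemaps import make_ratemap, speed_filter
from .remapping import (
    build_null,
    classify_cell,
    correct_orientation,
    correlate_maps,
    detect_ensemble_rotation,
    realign_to_box,
    single_compartment_comparison,
)
from .selection import detect_fields, qc_unit, shuffle_test
from .synth import SessionBundle, TrackedUnit
from .tracking import dedupe, match_cells, train_matcher, training_pairs_from_corpus

TWO_BOX_TRIALS = ("baseline1", "rotation", "baseline2")


@dataclass
class PipelineReport:
    admission: pd.DataFrame
    remap_results: list
    proportions: dict
    nulls: dict
    orientations: dict  # (session_id, trial name) -> EnsembleOrientation
    odor_retrieval: object | None
    preference: list
    tracking: dict | None
    summary: dict
    maps: dict = field(default_factory=dict, repr=False)


def _trial_map(trial, filtered, geometry, cfg: PipelineConfig):
    ext = rotated_extent(trial.rotation_deg, geometry.width, geometry.height)
    m = make_ratemap(
        filtered,
        ext,
        bin_size=cfg.bin_size,
        sigma=cfg.smoothing_sigma,
        cutoff=cfg.smoothing_cutoff,
        min_dwell=cfg.min_dwell,
    )
    return realign_to_box(m, trial.rotation_deg)


def _admit_session(bundle: SessionBundle, cfg: PipelineConfig, rng):
    """Admission table rows and box-frame rate maps for one session."""
    geometry = bundle.geometry
    trials = {t.name: t for t in bundle.trials}
    has_baselines = "baseline1" in trials and "baseline2" in trials
    rows = []
    maps = {name: {} for name in trials}
    cell_ids = sorted({cid for t in bundle.trials for cid in t.spikes})
    for cid in cell_ids:
        filtered = {
            name: speed_filter(t.traj, t.spikes[cid], cfg.speed_min, cfg.speed_max)
            for name, t in trials.items()
            if cid in t.spikes
        }
        row = {
            "session": bundle.session_id,
            "cell": cid,
            "admitted": False,
            "reason": "",
            "isi_violation_fraction": np.nan,
            "rate_baseline1": np.nan,
            "rate_baseline2": np.nan,
            "peak_trough_us": np.nan,
            "n_fields": 0,
            "messy": False,
            "spatial_info": np.nan,
            "info_threshold": np.nan,
        }
        if not has_baselines:
            row["reason"] = "missing_baseline"
            rows.append(row)
            continue
        wf = trials["baseline1"].waveforms.get(cid)
        qc = qc_unit(
            filtered,
            wf,
            isi_refractory=cfg.isi_refractory,
            isi_max_fraction=cfg.isi_max_fraction,
            rate_range=(cfg.rate_min, cfg.rate_max),
            peak_trough_min_us=cfg.peak_trough_min_us,
        )
        row.update(
            isi_violation_fraction=qc.isi_violation_fraction,
            rate_baseline1=qc.mean_rate_baseline1,
            rate_baseline2=qc.mean_rate_baseline2,
            peak_trough_us=qc.peak_trough_us,
        )
        if not qc.passed:
            row["reason"] = "qc:" + "+".join(qc.reasons)
            rows.append(row)
            continue
        for name in trials:
            maps[name][cid] = _trial_map(trials[name], filtered[name], geometry, cfg)
        m1 = maps["baseline1"][cid]
        fields, messy = detect_fields(
            m1,
            min_pixels=cfg.field_min_pixels,
            frac_of_peak=cfg.field_frac_of_peak,
            peak_min=cfg.field_peak_min,
            messy_fraction=cfg.messy_fraction,
            connectivity=cfg.field_connectivity,
        )
        row.update(n_fields=len(fields), messy=messy)
        if messy:
            row["reason"] = "messy"
            rows.append(row)
            continue
        if not fields:
            row["reason"] = "no_field"
            rows.append(row)
            continue
        sres = shuffle_test(
            trials["baseline1"].traj,
            trials["baseline1"].spikes[cid],
            (geometry.width, geometry.height),
            n_shuffles=cfg.n_shuffles,
            margin=cfg.shuffle_margin,
            seed=int(rng.integers(2**31)),
            bin_size=cfg.bin_size,
            sigma=cfg.smoothing_sigma,
            cutoff=cfg.smoothing_cutoff,
            min_dwell=cfg.min_dwell,
            percentile=cfg.info_percentile,
        )
        row.update(spatial_info=sres.info, info_threshold=sres.percentile_95)
        if not sres.is_spatial:
            row["reason"] = "not_spatial"
            rows.append(row)
            continue
        row.update(admitted=True, reason="admitted")
        rows.append(row)
    return rows, maps


def run_pipeline(
    bundles: list,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> PipelineReport:
    """Run the complete analysis over one or more session bundles."""

    cfg = config or PipelineConfig()
    if isinstance(bundles, SessionBundle):
        bundles = [bundles]
    bundles = [
        b if isinstance(b, SessionBundle) else tbio.read_session(b) for b in bundles
    ]
    rng = np.random.default_rng(cfg.seed)
    geometry = bundles[0].geometry

    admission_rows = []
    session_maps = {}
    for bundle in bundles:
        rows, maps = _admit_session(bundle, cfg, rng)
        admission_rows.extend(rows)
        session_maps[bundle.session_id] = maps
    admission = pd.DataFrame(admission_rows)
    admitted = {
        (r["session"], r["cell"]) for r in admission_rows if r["admitted"]
    }

    # ---- duplicate-cell removal across sessions --------------------------
    tracking = None
    unique = set(admitted)
    if len(bundles) > 1 and admitted:
        corpus = []
        for s, bundle in enumerate(bundles):
            tet = {c.cell_id: c.tetrode for c in bundle.cells}
            units = []
            for cid in sorted(
                cid for (sid, cid) in admitted if sid == bundle.session_id
            ):
                trials = {t.name: t for t in bundle.trials}
                trial_wfs = [
                    trials[n].waveforms[cid]
                    for n in TWO_BOX_TRIALS
                    if n in trials and cid in trials[n].waveforms
                ]
                units.append(
                    TrackedUnit(
                        label=f"{bundle.session_id}:{cid}",
                        true_id="",
                        session=s,
                        tetrode=tet.get(cid, 0),
                        waveform=trials["baseline1"].waveforms.get(cid),
                        trial_waveforms=trial_wfs,
                        ratemap=session_maps[bundle.session_id]["baseline1"][cid].rate,
                    )
                )
            corpus.append(units)
        try:
            same, different = training_pairs_from_corpus(corpus)
            matcher = train_matcher(same, different)
            decisions = match_cells(
                corpus,
                matcher,
                spatial_threshold=cfg.spatial_prescreen,
                posterior_min=cfg.posterior_min,
                posterior_gap=cfg.posterior_gap,
            )
            dd = dedupe(decisions, corpus)
            removed_labels = {lbl for _, lbl in dd["removed"]}
            unique = {
                (sid, cid)
                for (sid, cid) in admitted
                if f"{sid}:{cid}" not in removed_labels
            }
            tracking = {
                "decisions": decisions,
                "dedupe": dd,
                "matcher_accuracy": matcher.training_accuracy,
            }
        except ValueError as exc:  # not enough training pairs on tiny runs
            tracking = {"skipped": str(exc)}

    # ---- null thresholds -------------------------------------------------
    from .remapping import split_compartments

    whole_maps, whole_ids, sub_maps, sub_ids = [], [], [], []
    for bundle in bundles:
        maps = session_maps[bundle.session_id]
        for name in TWO_BOX_TRIALS:
            for cid, m in maps.get(name, {}).items():
                if (bundle.session_id, cid) not in unique:
                    continue
                whole_maps.append(m.rate)
                whole_ids.append((bundle.session_id, cid))
                s1, s2 = split_compartments(m, geometry)
                sub_maps.extend([s1, s2])
                sub_ids.extend([(bundle.session_id, cid)] * 2)
    nulls = {}
    try:
        nulls["whole"] = build_null(
            whole_maps, whole_ids, "whole", n=cfg.null_n,
            seed=int(rng.integers(2**31)), percentile=cfg.null_percentile,
            min_bins=cfg.min_joint_bins,
        )
        nulls["sub"] = build_null(
            sub_maps, sub_ids, "sub", n=cfg.null_n,
            seed=int(rng.integers(2**31)), percentile=cfg.null_percentile,
            min_bins=cfg.min_joint_bins,
        )
    except ValueError:
        nulls = {}
    thr_whole = nulls["whole"].threshold if nulls else float("nan")
    thr_sub = nulls["sub"].threshold if nulls else float("nan")

    # ---- ensemble orientation and correction -----------------------------
    orientations = {}
    corrected_maps = {}
    for bundle in bundles:
        sid = bundle.session_id
        maps = session_maps[sid]
        flags = {}
        if nulls and "baseline1" in maps:
            base = {
                cid: m for cid, m in maps["baseline1"].items()
                if (sid, cid) in unique
            }
            for name in ("rotation", "baseline2"):
                if name not in maps:
                    continue
                other = {
                    cid: m for cid, m in maps[name].items() if cid in base
                }
                try:
                    ori = detect_ensemble_rotation(
                        base, other, thr_whole, trial_pair=("baseline1", name)
                    )
                    orientations[(sid, name)] = ori
                    flags[name] = ori.switched if ori.determined else False
                except ValueError:
                    flags[name] = False
        cm, _ = correct_orientation(maps, flags)
        corrected_maps[sid] = cm

    # ---- classification --------------------------------------------------
    remap_results = []
    for bundle in bundles:
        sid = bundle.session_id
        maps = corrected_maps[sid]
        if not nulls or "baseline1" not in maps:
            continue
        for cid in sorted(maps["baseline1"]):
            if (sid, cid) not in unique:
                continue
            m1 = maps["baseline1"][cid]
            stab = (
                correlate_maps(m1, maps["baseline2"][cid], "none").r
                if cid in maps.get("baseline2", {})
                else float("nan")
            )
            cue = (
                correlate_maps(m1, maps["rotation"][cid], "none").r
                if cid in maps.get("rotation", {})
                else float("nan")
            )
            res = classify_cell(
                m1,
                geometry,
                thr_sub,
                cell_id=f"{sid}:{cid}",
                stability_r=stab,
                cue_control_r=cue,
                silent_peak=cfg.field_peak_min,
            )
            if np.isfinite(cue) and cue <= thr_whole:
                res.notes.append("excluded_no_cue_control")
            if np.isfinite(stab) and stab <= thr_whole:
                res.notes.append("excluded_unstable")
            remap_results.append(res)

    included = [
        r for r in remap_results
        if not any(n.startswith("excluded") for n in r.notes)
    ]
    informative = [r for r in included if r.category != "ambiguous"]
    n_inf = len(informative)
    proportions = {
        cat: (sum(r.category == cat for r in informative) / n_inf if n_inf else 0.0)
        for cat in ("repeat", "remap", "rotate")
    }
    proportions["n_classified"] = n_inf
    proportions["n_ambiguous"] = len(included) - n_inf

    # ---- single-compartment odor retrieval -------------------------------
    odor = None
    for bundle in bundles:
        sid = bundle.session_id
        maps = corrected_maps[sid]
        singles = {
            t.name: {
                cid: m for cid, m in maps.get(t.name, {}).items()
                if (sid, cid) in unique
            }
            for t in bundle.trials
            if not t.door_open
        }
        comps = {
            t.name: t.single_compartment for t in bundle.trials if not t.door_open
        }
        if singles and "rotation" in maps:
            rot = {
                cid: m for cid, m in maps["rotation"].items()
                if (sid, cid) in unique
            }
            try:
                res = single_compartment_comparison(rot, singles, comps, geometry)
            except ValueError:
                continue
            if odor is None:
                odor = res
            else:
                odor.records.extend(res.records)

    # ---- behavioral preference ------------------------------------------
    preference = []
    for bundle in bundles:
        for t in bundle.trials:
            if t.door_open:
                preference.append(
                    preference_index(
                        t.traj_box(bundle.geometry),
                        bundle.geometry,
                        trial_id=f"{bundle.session_id}:{t.name}",
                    )
                )

    summary = {
        "config_hash": cfg.hash,
        "config": cfg.to_dict(),
        "n_sessions": len(bundles),
        "n_cells": len(admission),
        "n_admitted": len(admitted),
        "n_unique": len(unique),
        "null_threshold_whole": thr_whole,
        "null_threshold_sub": thr_sub,
        "proportions": proportions,
        "switched_trials": {
            f"{sid}:{name}": ori.switched
            for (sid, name), ori in orientations.items()
        },
        "preference_index": {p.trial_id: p.pi for p in preference},
        "odor_retrieval": (
            {
                "median_same": odor.median_same,
                "median_diff": odor.median_diff,
                "median_paired_diff": odor.median_paired_diff,
                "wilcoxon_p": odor.wilcoxon_p,
            }
            if odor is not None
            else None
        ),
    }
    report = PipelineReport(
        admission=admission,
        remap_results=remap_results,
        proportions=proportions,
        nulls=nulls,
        orientations=orientations,
        odor_retrieval=odor,
        preference=preference,
        tracking=tracking,
        summary=summary,
        maps=corrected_maps,
    )
    if out_dir is not None:
        write_report(report, out_dir, cfg)
    return report


def write_report(report: PipelineReport, out_dir, cfg: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.admission.to_csv(
        out / "cells_admitted.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        [
            {
                "cell": r.cell_id,
                "r_translational": r.r_translational,
                "r_rotational": r.r_rotational,
                "threshold": r.threshold,
                "category": r.category,
                "low_confidence": r.low_confidence,
                "stability_r": r.stability_r,
                "cue_control_r": r.cue_control_r,
                "notes": ";".join(r.notes),
            }
            for r in report.remap_results
        ]
    ).to_csv(out / "remap_results.csv", index=False, float_format="%.6f")
    pd.DataFrame(
        [
            {
                "session": sid,
                "trial": name,
                "switched": ori.switched,
                "determined": ori.determined,
                "n_switched_cells": ori.n_switched_cells,
                "n_consistent_cells": ori.n_consistent_cells,
            }
            for (sid, name), ori in report.orientations.items()
        ]
    ).to_csv(out / "ensemble_orientation.csv", index=False)
    pd.DataFrame(
        [
            {"trial": p.trial_id, "t_vanilla": p.t_vanilla,
             "t_lemon": p.t_lemon, "pi": p.pi}
            for p in report.preference
        ]
    ).to_csv(out / "preference.csv", index=False, float_format="%.6f")
    if report.nulls:
        tbio.write_null_h5(report.nulls, out / "null_distributions.h5")
    if report.tracking and "decisions" in report.tracking:
        pd.DataFrame(
            [
                {
                    "cell_a": d.cell_a,
                    "cell_b": d.cell_b,
                    "boundary": f"{d.boundary[0]}-{d.boundary[1]}",
                    "d1": d.d1,
                    "d2": d.d2,
                    "spatial_r": d.spatial_r,
                    "posterior": d.posterior_same,
                    "decided_same": d.decided_same,
                    "resolution": d.resolution,
                }
                for d in report.tracking["decisions"]
            ]
        ).to_csv(out / "matches.csv", index=False, float_format="%.6f")
        pd.DataFrame(
            [{"session": s, "cell": lbl} for s, lbl in
             report.tracking["dedupe"]["kept"]]
        ).to_csv(out / "unique_cells.csv", index=False)
    tbio._dump_json(report.summary, out / "summary.json")
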