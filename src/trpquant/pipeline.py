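"""Config-driven end-to-end runs: simulate, analyze imaging, analyze ephys.

Each run reads its inputs (per-cell trace tables or paired TIFF stacks plus
an ROI table; ramp-sweep tables with capacitances), applies the
classification chain with explicit thresholds, and writes a report bundle:
per-cell classification CSV, subgroup count table, averaged traces with
SEM, inhibition values, size histogram, and a JSON log recording every
parameter and seed used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .classify import (
    ClassificationParams,
    classify_population,
    subgroup_2x2,
)
from .ephys import (
    RampSweepSeries,
    baseline_subtract_currents,
    ephys_inhibition,
    extract_currents,
    qc_min_response,
)
from .group_stats import average_trace, percentage, size_histogram
from .imaging import compute_ratio_stack, extract_roi_trace, feret_diameter, load_roi_table
from .traces import ApplicationSchedule, CellTrace, ScheduleEntry

__all__ = [
    "RunConfig",
    "load_schedule",
    "load_traces_csv",
    "run_imaging_pipeline",
    "run_ephys_pipeline",
    "run_simulation",
]


@dataclass
class RunConfig:
    """All parameters of one pipeline run, serialisable to YAML/JSON."""

    mode: str = "imaging"  # imaging | ephys | simulate
    outdir: str = "trpquant_out"
    # inputs
    traces_csv: str | None = None
    stack340: str | None = None
    stack380: str | None = None
    roi_table: str | None = None
    schedule: str | None = None
    sweeps_csv: str | None = None
    capacitance_csv: str | None = None
    diameters_csv: str | None = None
    # imaging parameters
    intensity_threshold: float | None = None  # required for image-based runs
    background_method: str | float = "percentile"
    um_per_px: float = 1.0
    # analysis thresholds
    theta_response: float = 0.1
    theta_inhibition: float = 7.5
    n_baseline: int = 20
    smooth_window: int = 5
    post_lag_frames: int = 2
    rounding_decimals: int = 1
    agonist_compound: str = "PS"
    caps_compound: str = "capsaicin"
    highk_compound: str = "high-K+"
    # ephys parameters
    potentials_mv: tuple = (-80.0, 80.0)
    ljp_mv: float = 15.0
    qc_threshold_pa: float = 10.0
    qc_direction: str = "inward"
    ephys_baseline_window: tuple = (0.0, 20.0)
    # simulation
    seed: int = 0
    n_cells: int | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def classification_params(self) -> ClassificationParams:
        return ClassificationParams(
            theta_response=self.theta_response,
            theta_inhibition=self.theta_inhibition,
            n_baseline=self.n_baseline,
            smooth_window=self.smooth_window,
            post_lag_frames=self.post_lag_frames,
        )


def load_schedule(path: str | Path) -> ApplicationSchedule:
    """Read an application schedule from a YAML or JSON entry list."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    return ApplicationSchedule(
        [
            ScheduleEntry(
                compound=e["compound"],
                concentration=str(e.get("concentration", "")),
                t_start=float(e["t_start"]),
                t_end=float(e["t_end"]),
                role=e["role"],
            )
            for e in raw
        ]
    )


def load_traces_csv(path: str | Path) -> list[CellTrace]:
    """Read a long-format trace table (time_s, cell_id, ratio)."""
    df = pd.read_csv(path)
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_s")
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                time=sub["time_s"].to_numpy(),
                ratio=sub["ratio"].to_numpy(),
            )
        )
    return traces


def _write_log(outdir: Path, config: RunConfig, extra: dict) -> None:
    log = {"config": dataclasses.asdict(config), **extra}
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


def run_imaging_pipeline(config: RunConfig) -> dict:
    """Classify a calcium-imaging experiment and write the report bundle."""
    if config.schedule is None:
        raise ValueError("an application schedule is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = load_schedule(config.schedule)

    diameters: dict[str, float] = {}
    if config.traces_csv is not None:
        traces = load_traces_csv(config.traces_csv)
    elif config.stack340 and config.stack380 and config.roi_table:
        if config.intensity_threshold is None:
            raise ValueError(
                "intensity_threshold must be set explicitly for image-based runs"
            )
        import tifffile

        stack340 = tifffile.imread(config.stack340)
        stack380 = tifffile.imread(config.stack380)
        rois = load_roi_table(config.roi_table)
        rstack = compute_ratio_stack(
            stack340, stack380, config.background_method, config.intensity_threshold
        )
        traces = [extract_roi_trace(rstack, roi) for roi in rois]
        diameters = {
            roi.roi_id: feret_diameter(roi, config.um_per_px) for roi in rois
        }
        for tr in traces:
            tr.diameter_um = diameters.get(tr.cell_id)
    else:
        raise ValueError("either traces_csv or stacks + roi_table required")

    if config.diameters_csv is not None:
        ddf = pd.read_csv(config.diameters_csv)
        diameters = dict(zip(ddf["cell_id"].astype(str), ddf["feret_um"]))
        for tr in traces:
            tr.diameter_um = diameters.get(tr.cell_id)

    params = config.classification_params()
    classifications = classify_population(
        traces, schedule, params,
        caps_compound=config.caps_compound,
        highk_compound=config.highk_compound,
    )
    cls_df = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "is_neuron": c.is_neuron,
                "excluded": c.excluded,
                "exclusion_reason": c.exclusion_reason,
                **{
                    f"responder_{compound}": v for compound, v in c.responder.items()
                },
                "inhibition_pct": c.inhibition_pct,
                "inhibitor_sensitive": c.inhibitor_sensitive,
                "inhibition_undefined": c.inhibition_undefined,
                "inhibition_artifact": c.inhibition_artifact,
                "diameter_um": c.diameter_um,
            }
            for c in classifications
        ]
    )
    cls_df.to_csv(outdir / "classifications.csv", index=False)

    groups, table = subgroup_2x2(
        classifications,
        agonist_compound=config.agonist_compound,
        caps_compound=config.caps_compound,
    )
    table.to_csv(outdir / "subgroup_counts.csv")

    neurons = [c for c in classifications if c.is_neuron]
    ps_cells = {
        c.cell_id for c in neurons if c.responder.get(config.agonist_compound)
    }
    notice = ""
    if not neurons:
        notice = "no cells passed the neuron gate; group outputs are empty"

    by_id = {tr.cell_id: tr for tr in traces}
    avg_rows = []
    for name, ids in groups.items():
        if not ids:
            continue
        summary = average_trace([by_id[i] for i in ids], name=name)
        for t, m, s in zip(summary.time, summary.mean, summary.sem):
            avg_rows.append(
                {"group": name, "time_s": t, "mean_ratio": m, "sem_ratio": s}
            )
    pd.DataFrame(avg_rows).to_csv(outdir / "average_traces.csv", index=False)

    inh_df = cls_df[cls_df["cell_id"].isin(ps_cells)][
        ["cell_id", "inhibition_pct", "inhibitor_sensitive"]
    ]
    inh_df.to_csv(outdir / "inhibition_values.csv", index=False)

    n_ps = len(ps_cells)
    n_inh = int(sum(c.inhibitor_sensitive for c in neurons))
    summary = {
        "n_cells": len(classifications),
        "n_neurons": len(neurons),
        "n_agonist_sensitive": n_ps,
        "n_inhibitor_sensitive": n_inh,
        "pct_inhibitor_sensitive_of_agonist": (
            percentage(n_inh, n_ps, config.rounding_decimals) if n_ps else None
        ),
        "subgroup_counts": {k: len(v) for k, v in groups.items()},
        "notice": notice,
    }
    diam_values = [c.diameter_um for c in neurons if c.diameter_um is not None]
    if diam_values:
        hist, frac_above = size_histogram([d for d in diam_values if d > 0])
        hist.to_csv(outdir / "size_histogram.csv", index=False)
        summary["fraction_diameter_above_31um"] = frac_above
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_log(outdir, config, {"n_traces": len(traces)})
    return summary


def _load_sweeps(config: RunConfig) -> list[RampSweepSeries]:
    """Read ramp sweeps (cell_id, sweep_time_s, voltage_mV, current_pA) plus
    a capacitance table (cell_id, capacitance_pF)."""
    sweeps = pd.read_csv(config.sweeps_csv)
    caps = pd.read_csv(config.capacitance_csv)
    cap_map = dict(zip(caps["cell_id"].astype(str), caps["capacitance_pF"]))
    series = []
    for cell_id, sub in sweeps.groupby("cell_id", sort=True):
        cell_id = str(cell_id)
        if cell_id not in cap_map:
            continue  # excluded downstream with a logged reason
        times = np.sort(sub["sweep_time_s"].unique())
        first = sub[sub["sweep_time_s"] == times[0]].sort_values("voltage_mV")
        command = first["voltage_mV"].to_numpy()
        currents = np.vstack(
            [
                sub[sub["sweep_time_s"] == t].sort_values("voltage_mV")[
                    "current_pA"
                ].to_numpy()
                for t in times
            ]
        )
        series.append(
            RampSweepSeries(
                cell_id=cell_id, sweep_times=times,
                command_voltage_mv=command, current_pa=currents,
                capacitance_pf=float(cap_map[cell_id]), ljp_mv=config.ljp_mv,
            )
        )
    return series


def run_ephys_pipeline(config: RunConfig) -> dict:
    """Analyze a cohort of ramp recordings and write the report bundle."""
    if config.sweeps_csv is None or config.capacitance_csv is None:
        raise ValueError("sweeps_csv and capacitance_csv are required")
    if config.schedule is None:
        raise ValueError("an application schedule is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = load_schedule(config.schedule)
    series = _load_sweeps(config)

    all_ids = set(
        pd.read_csv(config.sweeps_csv)["cell_id"].astype(str).unique()
    )
    with_cap = {s.cell_id for s in series}
    excluded = [
        {"cell_id": i, "reason": "missing capacitance"}
        for i in sorted(all_ids - with_cap)
    ]

    agonist_entries = schedule.with_role("agonist")
    agonist_window = (
        agonist_entries[0].t_start,
        agonist_entries[-1].t_end,
    )
    rows = []
    tc_rows = []
    for s in series:
        tc = extract_currents(s, tuple(config.potentials_mv))
        tc = baseline_subtract_currents(tc, tuple(config.ephys_baseline_window))
        passed = qc_min_response(
            tc, agonist_window, config.qc_threshold_pa, config.qc_direction
        )
        record = {"cell_id": s.cell_id, "qc_pass": passed}
        if passed:
            inh = ephys_inhibition(tc, schedule)
            for p, v in inh.items():
                record[f"inhibition_pct_at_{p:+.0f}mV"] = v
        rows.append(record)
        dens = tc.density_pa_pf
        for i, t in enumerate(tc.sweep_times):
            for j, p in enumerate(tc.potentials_mv):
                tc_rows.append(
                    {
                        "cell_id": s.cell_id, "sweep_time_s": t,
                        "potential_mV": p,
                        "current_pA": tc.current_pa[i, j],
                        "density_pA_pF": dens[i, j],
                    }
                )
    result_df = pd.DataFrame(rows)
    result_df.to_csv(outdir / "ephys_inhibition.csv", index=False)
    pd.DataFrame(tc_rows).to_csv(outdir / "current_timecourses.csv", index=False)
    pd.DataFrame(
        excluded + [
            {"cell_id": r["cell_id"], "reason": "failed 10 pA QC"}
            for r in rows if not r["qc_pass"]
        ]
    ).to_csv(outdir / "excluded_cells.csv", index=False)

    qc_passed = result_df[result_df["qc_pass"]] if len(result_df) else result_df
    notice = "" if len(qc_passed) else "no cell passed the minimum-response QC"
    summary: dict = {
        "n_cells": len(all_ids),
        "n_with_capacitance": len(series),
        "n_qc_passed": int(len(qc_passed)),
        "notice": notice,
    }
    for p in config.potentials_mv:
        col = f"inhibition_pct_at_{p:+.0f}mV"
        if col in qc_passed:
            summary[f"mean_{col}"] = float(qc_passed[col].mean())
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_log(outdir, config, {"n_excluded": len(excluded)})
    return summary


def run_simulation(config: RunConfig) -> dict:
    """Generate a synthetic dataset under the default study conditions."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kwargs = {"seed": config.seed}
    if config.n_cells is not None:
        kwargs["n_cells"] = config.n_cells
    pop_config = synthetic.SyntheticPopulationConfig(**kwargs)
    paths = synthetic.write_dataset(outdir, pop_config)
    _write_log(outdir, config, {"outputs": {k: str(v) for k, v in paths.items()}})
    return {k: str(v) for k, v in paths.items()}
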