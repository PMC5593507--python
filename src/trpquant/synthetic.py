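"""Synthetic labeled populations of sensory-neuron calcium recordings.

The generator emulates the mixed DRG-neuron cultures the analysis chain is
designed for: a fraction of the cells are neurons (identified by their
response to high-K+ depolarization or capsaicin), a subset of the neurons
respond to the TRPM3 agonist pregnenolone sulfate (PS), capsaicin
sensitivity marks TRPV1-expressing cells, and a subset of the PS responders
is inhibited by a GPCR agonist (e.g. the µ-opioid agonist DAMGO) applied on
top of one PS application.  Responses run down multiplicatively across
repeated agonist applications, and traces carry i.i.d. Gaussian noise and
an optional linear baseline drift.  Every generated cell comes with its
ground-truth labels, so recovery of the labels by the analysis chain can be
tested quantitatively.

The default configuration mirrors a large mixed-culture experiment:
3,576 neurons of which 17.2% are PS-sensitive; within the PS-sensitive
pool 78% are capsaicin-sensitive, and inhibitor sensitivity is 97% among
capsaicin-positive and 72% among capsaicin-negative PS responders.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import RampSweepSeries
from .traces import ApplicationSchedule, CellTrace, ScheduleEntry

__all__ = [
    "SyntheticPopulationConfig",
    "GroundTruthLabel",
    "CellEllipse",
    "FieldGeometry",
    "RampSimParams",
    "default_schedule",
    "generate_population",
    "render_image_stacks",
    "generate_ramp_recording",
    "write_dataset",
]


def default_schedule(
    *,
    agonist: str = "PS",
    inhibitor: str = "DAMGO",
    frame_interval: float = 5.0,
) -> ApplicationSchedule:
    """Three agonist applications with the inhibitor over the second one,
    followed by capsaicin and the end-of-experiment high-K+ depolarization."""
    return ApplicationSchedule(
        [
            ScheduleEntry(agonist, "25 uM", 120.0, 180.0, "agonist"),
            ScheduleEntry(inhibitor, "3 uM", 250.0, 350.0, "inhibitor"),
            ScheduleEntry(agonist, "25 uM", 270.0, 330.0, "agonist"),
            ScheduleEntry(agonist, "25 uM", 420.0, 480.0, "agonist"),
            ScheduleEntry("capsaicin", "2 uM", 570.0, 600.0, "agonist"),
            ScheduleEntry("high-K+", "39 mM", 690.0, 720.0, "depolarization"),
        ]
    )


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Generative parameters for a labeled synthetic cell population.

    Fractions are conditional probabilities along the label hierarchy
    non-neuron -> neuron -> PS-sensitive -> capsaicin-/inhibitor-sensitive.
    ``frac_inhibitor_sensitive_given_ps_caps`` and ``..._nocaps`` allow the
    inhibitor-sensitive fraction to differ between capsaicin-positive and
    -negative PS responders (they are strongly associated in real DRG
    cultures); when left at None the marginal
    ``frac_inhibitor_sensitive_given_ps`` applies to both.
    """

    n_cells: int = 3576
    frac_neuron: float = 1.0
    frac_ps_sensitive: float = 614 / 3576
    frac_caps_sensitive_given_ps: float = 479 / 614
    frac_caps_sensitive_given_not_ps: float = 1289 / 2962
    frac_inhibitor_sensitive_given_ps: float = 562 / 614
    frac_inhibitor_sensitive_given_ps_caps: float | None = 465 / 479
    frac_inhibitor_sensitive_given_ps_nocaps: float | None = 97 / 135
    inhibition_depth: float = 0.5
    ps_amplitude_mean: float = 0.5
    ps_amplitude_sd: float = 0.1
    caps_amplitude_mean: float = 0.5
    caps_amplitude_sd: float = 0.1
    highk_amplitude_mean: float = 1.0
    rundown_factor: float = 0.9
    drift_slope: float = 0.0  # ratio units per frame
    noise_sd: float = 0.05
    baseline_ratio: float = 0.5
    frame_interval: float = 5.0
    neuron_diameter_mean_um: float = 22.0
    neuron_diameter_sd_um: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_neuron": self.frac_neuron,
            "frac_ps_sensitive": self.frac_ps_sensitive,
            "frac_caps_sensitive_given_ps": self.frac_caps_sensitive_given_ps,
            "frac_caps_sensitive_given_not_ps": self.frac_caps_sensitive_given_not_ps,
            "frac_inhibitor_sensitive_given_ps": self.frac_inhibitor_sensitive_given_ps,
            "inhibition_depth": self.inhibition_depth,
        }
        for name in (
            "frac_inhibitor_sensitive_given_ps_caps",
            "frac_inhibitor_sensitive_given_ps_nocaps",
        ):
            v = getattr(self, name)
            if v is not None:
                fracs[name] = v
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "ps_amplitude_mean", "ps_amplitude_sd", "caps_amplitude_mean",
            "caps_amplitude_sd", "highk_amplitude_mean", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.rundown_factor <= 1.0:
            raise ValueError("rundown_factor must lie in (0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")


@dataclass(frozen=True)
class GroundTruthLabel:
    cell_id: str
    is_neuron: bool
    ps_sensitive: bool
    caps_sensitive: bool
    inhibitor_sensitive: bool
    true_inhibition: float  # percent; NaN for PS-insensitive cells
    true_diameter: float  # um


# rise-plateau-decay response kernel: linear rise over RISE_FRAMES frames,
# plateau for the application window, then an exponential decay (tau = 6
# frames) shifted and scaled to reach exactly zero DECAY_CUTOFF_FRAMES after
# washout, so sufficiently spaced applications do not bleed into each other
RISE_FRAMES = 3
DECAY_TAU_FRAMES = 6.0
DECAY_CUTOFF_FRAMES = 18


def _transient(time: np.ndarray, t0: float, t1: float, dt: float) -> np.ndarray:
    """Unit-amplitude rise-plateau-decay kernel for one application window."""
    rise = np.clip((time - t0) / (RISE_FRAMES * dt), 0.0, 1.0)
    cutoff = DECAY_CUTOFF_FRAMES * dt
    floor = np.exp(-DECAY_CUTOFF_FRAMES / DECAY_TAU_FRAMES)
    raw = np.exp(-np.clip(time - t1, 0.0, cutoff) / (DECAY_TAU_FRAMES * dt))
    decay = np.where(time <= t1, 1.0, (raw - floor) / (1.0 - floor))
    return np.where(time < t0, 0.0, rise * np.clip(decay, 0.0, 1.0))


def generate_population(
    config: SyntheticPopulationConfig,
    schedule: ApplicationSchedule | None = None,
) -> tuple[list[CellTrace], list[GroundTruthLabel]]:
    """Generate labeled ratio traces for one synthetic population.

    PS-sensitive cells show a transient in every PS window with amplitude
    scaled by ``rundown_factor**(k-1)`` for the k-th application;
    inhibitor-sensitive cells additionally have PS responses in
    inhibitor-overlapping windows multiplied by ``1 - inhibition_depth``.
    Capsaicin and high-K+ responses are analogous; non-neurons respond to
    nothing.  Gaussian noise and linear drift are added last, after the
    noise-free ground-truth inhibition has been recorded.
    """
    if schedule is None:
        schedule = default_schedule(frame_interval=config.frame_interval)
    rng = np.random.default_rng(config.seed)

    dt = config.frame_interval
    n_frames = int(np.ceil(schedule.t_end / dt)) + 8  # room for the final decay
    time = np.arange(n_frames) * dt
    if schedule.t_end > time[-1]:
        raise ValueError("schedule windows exceed the generated time axis")

    inhibitor_entries = schedule.with_role("inhibitor")

    traces: list[CellTrace] = []
    labels: list[GroundTruthLabel] = []
    for i in range(config.n_cells):
        cell_id = f"cell{i:05d}"
        is_neuron = bool(rng.random() < config.frac_neuron)
        ps = bool(is_neuron and rng.random() < config.frac_ps_sensitive)
        if ps:
            p_caps = config.frac_caps_sensitive_given_ps
        else:
            p_caps = config.frac_caps_sensitive_given_not_ps
        caps = bool(is_neuron and rng.random() < p_caps)
        if ps:
            if caps and config.frac_inhibitor_sensitive_given_ps_caps is not None:
                p_inh = config.frac_inhibitor_sensitive_given_ps_caps
            elif (
                not caps
                and config.frac_inhibitor_sensitive_given_ps_nocaps is not None
            ):
                p_inh = config.frac_inhibitor_sensitive_given_ps_nocaps
            else:
                p_inh = config.frac_inhibitor_sensitive_given_ps
            inh = bool(rng.random() < p_inh)
        else:
            inh = False

        ps_amp = max(
            0.0, rng.normal(config.ps_amplitude_mean, config.ps_amplitude_sd)
        )
        caps_amp = max(
            0.0, rng.normal(config.caps_amplitude_mean, config.caps_amplitude_sd)
        )
        highk_amp = config.highk_amplitude_mean
        if is_neuron:
            diameter = float(
                np.clip(
                    rng.normal(
                        config.neuron_diameter_mean_um,
                        config.neuron_diameter_sd_um,
                    ),
                    8.0,
                    45.0,
                )
            )
        else:
            diameter = float(np.clip(rng.normal(14.0, 3.0), 5.0, 30.0))

        ratio = np.full(n_frames, config.baseline_ratio)
        responded: dict[str, list[float]] = {}
        for compound in schedule.compounds():
            apps = [
                e for e in schedule.applications(compound)
                if e.role in ("agonist", "depolarization")
            ]
            for k, entry in enumerate(apps):
                if compound == "capsaicin":
                    amp = caps_amp if (is_neuron and caps) else 0.0
                elif entry.role == "depolarization":
                    amp = highk_amp if is_neuron else 0.0
                elif compound == schedule.compounds()[0] or entry.role == "agonist":
                    # principal agonist (PS by default)
                    amp = ps_amp if ps else 0.0
                amp *= config.rundown_factor ** k
                overlapped = any(entry.overlaps(x) for x in inhibitor_entries)
                if overlapped and inh:
                    amp *= 1.0 - config.inhibition_depth
                responded.setdefault(compound, []).append(amp)
                if amp > 0:
                    ratio += amp * _transient(time, entry.t_start, entry.t_end, dt)

        # noise-free ground-truth inhibition from the constructed amplitudes
        true_inh = float("nan")
        if inhibitor_entries:
            agonist = schedule.with_role("agonist")
            overlapped = [
                e for e in agonist if e.overlaps(inhibitor_entries[0])
            ]
            if overlapped and ps:
                compound = overlapped[0].compound
                apps = [
                    e for e in schedule.applications(compound)
                    if e.role == "agonist"
                ]
                k = apps.index(overlapped[0])
                amps = responded[compound]
                denom = amps[k - 1] + amps[k + 1] if 0 < k < len(amps) - 1 else 0.0
                if denom > 0:
                    true_inh = 100.0 * (1.0 - 2.0 * amps[k] / denom)

        ratio += config.drift_slope * np.arange(n_frames)
        if config.noise_sd > 0:
            ratio += rng.normal(0.0, config.noise_sd, n_frames)

        traces.append(
            CellTrace(
                cell_id=cell_id, time=time.copy(), ratio=ratio,
                recording_id="synthetic", diameter_um=diameter,
            )
        )
        labels.append(
            GroundTruthLabel(
                cell_id=cell_id, is_neuron=is_neuron, ps_sensitive=ps,
                caps_sensitive=caps, inhibitor_sensitive=inh,
                true_inhibition=true_inh, true_diameter=diameter,
            )
        )
    return traces, labels


@dataclass(frozen=True)
class CellEllipse:
    """Elliptical cell footprint in the imaging field (pixel units)."""

    roi_id: str
    center_x_px: float
    center_y_px: float
    semi_axis_a_px: float
    semi_axis_b_px: float
    orientation_rad: float = 0.0


@dataclass(frozen=True)
class FieldGeometry:
    width_px: int = 128
    height_px: int = 128
    um_per_px: float = 1.0


def _ellipse_mask(e: CellEllipse, shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - e.center_x_px
    dy = yy - e.center_y_px
    c, s = np.cos(e.orientation_rad), np.sin(e.orientation_rad)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / e.semi_axis_a_px) ** 2 + (v / e.semi_axis_b_px) ** 2 <= 1.0


def render_image_stacks(
    cells: list[CellTrace],
    geometry: list[CellEllipse],
    fieldgeo: FieldGeometry = FieldGeometry(),
    *,
    background_intensity: int = 100,
    cell_f380_intensity: int = 20000,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render paired 340/380 nm 16-bit image stacks from ratio traces.

    Each cell's 380 nm intensity is constant; the 340 nm intensity above
    background is the 380 nm intensity above background times the cell's
    ratio at that frame, so the ratio-stack computation recovers the input
    traces up to integer quantization.  Overlapping ellipses are rejected
    to keep the ROI ground truth unambiguous.
    """
    if len(cells) != len(geometry):
        raise ValueError("one ellipse per cell trace required")
    shape = (fieldgeo.height_px, fieldgeo.width_px)
    if fieldgeo.um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    masks = []
    for e in geometry:
        r = max(e.semi_axis_a_px, e.semi_axis_b_px)
        if (
            e.center_x_px - r < 0
            or e.center_x_px + r > fieldgeo.width_px - 1
            or e.center_y_px - r < 0
            or e.center_y_px + r > fieldgeo.height_px - 1
        ):
            raise ValueError(f"ellipse {e.roi_id} does not fit inside the field")
        masks.append(_ellipse_mask(e, shape))
    combined = np.zeros(shape, dtype=int)
    for m in masks:
        combined += m
    if np.any(combined > 1):
        raise ValueError("overlapping cell ellipses are not supported")

    n_frames = len(cells[0])
    if any(len(c) != n_frames for c in cells):
        raise ValueError("all traces must share one time grid")
    bg = background_intensity
    net380 = cell_f380_intensity - bg
    stack380 = np.full((n_frames,) + shape, bg, dtype=np.uint16)
    stack340 = np.full((n_frames,) + shape, bg, dtype=np.uint16)
    for trace, mask in zip(cells, masks):
        stack380[:, mask] = cell_f380_intensity
        f340 = bg + net380 * trace.ratio[:, None]
        stack340[:, mask] = np.clip(np.round(f340), 0, 65535).astype(np.uint16)

    roi_table = pd.DataFrame(
        [
            {
                "roi_id": e.roi_id,
                "center_x_px": e.center_x_px,
                "center_y_px": e.center_y_px,
                "semi_axis_a_px": e.semi_axis_a_px,
                "semi_axis_b_px": e.semi_axis_b_px,
                "orientation_rad": e.orientation_rad,
            }
            for e in geometry
        ]
    )
    return stack340, stack380, roi_table


@dataclass(frozen=True)
class RampSimParams:
    """Parameters for a synthetic whole-cell voltage-ramp recording.

    The command ramp runs from -100 to +100 mV at 1 mV/ms; after the
    liquid-junction-potential correction (15 mV) the reported potentials
    span -115 to +85 mV.  The channel conductance is active during agonist
    windows and scaled by ``inhibitor_scale`` during inhibitor windows.
    """

    conductance_ns: float = 1.0
    reversal_mv: float = 0.0
    rectification: str = "outward"  # "outward" or "ohmic"
    agonist_windows: tuple[tuple[float, float], ...] = ((30.0, 150.0),)
    inhibitor_windows: tuple[tuple[float, float], ...] = ((70.0, 110.0),)
    inhibitor_scale: float = 0.1
    noise_pa: float = 0.0
    sweep_period_s: float = 2.0
    duration_s: float = 180.0
    command_start_mv: float = -100.0
    command_end_mv: float = 100.0
    ljp_mv: float = 15.0
    capacitance_pf: float = 10.0
    holding_mv: float = -15.0
    seed: int = 0


def _in_any(t: float, windows: tuple[tuple[float, float], ...]) -> bool:
    return any(a <= t <= b for a, b in windows)


def generate_ramp_recording(
    params: RampSimParams = RampSimParams(), cell_id: str = "cell0"
) -> RampSweepSeries:
    """Simulate ramp sweeps with a known agonist/inhibitor time course."""
    rng = np.random.default_rng(params.seed)
    command = np.arange(params.command_start_mv, params.command_end_mv + 0.5, 1.0)
    v_true = command - params.ljp_mv
    if params.rectification == "ohmic":
        rect = np.ones_like(v_true)
    elif params.rectification == "outward":
        rect = 1.0 / (1.0 + np.exp(-v_true / 25.0))
    else:
        raise ValueError(f"unknown rectification {params.rectification!r}")
    base_iv = params.conductance_ns * (v_true - params.reversal_mv) * rect  # pA

    sweep_times = np.arange(0.0, params.duration_s, params.sweep_period_s)
    currents = np.zeros((len(sweep_times), len(command)))
    for j, t in enumerate(sweep_times):
        active = 1.0 if _in_any(t, params.agonist_windows) else 0.0
        scale = params.inhibitor_scale if _in_any(t, params.inhibitor_windows) else 1.0
        iv = active * scale * base_iv
        if params.noise_pa > 0:
            iv = iv + rng.normal(0.0, params.noise_pa, len(command))
        currents[j] = iv
    return RampSweepSeries(
        cell_id=cell_id,
        sweep_times=sweep_times,
        command_voltage_mv=command,
        current_pa=currents,
        capacitance_pf=params.capacitance_pf,
        ljp_mv=params.ljp_mv,
        holding_mv=params.holding_mv,
    )


def write_dataset(
    outdir: str | Path,
    config: SyntheticPopulationConfig,
    schedule: ApplicationSchedule | None = None,
) -> dict[str, Path]:
    """Generate a population and write the standard CSV/JSON artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if schedule is None:
        schedule = default_schedule(frame_interval=config.frame_interval)
    traces, labels = generate_population(config, schedule)

    trace_rows = []
    for tr in traces:
        for t, r in zip(tr.time, tr.ratio):
            trace_rows.append({"time_s": t, "cell_id": tr.cell_id, "ratio": r})
    paths = {
        "traces": outdir / "traces.csv",
        "labels": outdir / "labels.csv",
        "schedule": outdir / "schedule.json",
        "config": outdir / "config.json",
        "diameters": outdir / "diameters.csv",
    }
    pd.DataFrame(trace_rows).to_csv(paths["traces"], index=False)
    pd.DataFrame([asdict(l) for l in labels]).to_csv(paths["labels"], index=False)
    with open(paths["schedule"], "w") as fh:
        json.dump(
            [
                {
                    "compound": e.compound, "concentration": e.concentration,
                    "t_start": e.t_start, "t_end": e.t_end, "role": e.role,
                }
                for e in schedule.entries
            ],
            fh,
            indent=2,
        )
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    pd.DataFrame(
        [{"cell_id": tr.cell_id, "feret_um": tr.diameter_um} for tr in traces]
    ).to_csv(paths["diameters"], index=False)
    return paths
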