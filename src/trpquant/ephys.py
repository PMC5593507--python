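"""Whole-cell voltage-ramp current analysis.

Voltage ramps (1 mV/ms) are applied every 1-2 s; membrane currents are read
offline at fixed potentials (typically -80 and +80 mV) after correcting the
command voltage for the calculated liquid junction potential (LJP, 15 mV in
the standard solutions, 0 in Cs+-free mode).  Currents are normalized by
cell capacitance to current densities (pA/pF), baseline-subtracted, gated
by a minimum-response quality criterion (>10 pA agonist-evoked current),
and inhibition is quantified with the same before/during/after statistic
used for the imaging data (capacitance cancels, so currents and densities
give identical inhibition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .classify import inhibition
from .traces import ApplicationSchedule

__all__ = [
    "RampSweepSeries",
    "CurrentTimeCourse",
    "extract_currents",
    "baseline_subtract_currents",
    "qc_min_response",
    "ephys_inhibition",
]


@dataclass
class RampSweepSeries:
    """Time-stamped voltage-ramp recordings from one patched cell.

    ``command_voltage_mv`` holds the uncorrected command ramp shared by all
    sweeps; the reported (corrected) membrane potential is
    ``command_voltage_mv - ljp_mv``.
    """

    cell_id: str
    sweep_times: np.ndarray  # (n_sweeps,) seconds
    command_voltage_mv: np.ndarray  # (n_samples,)
    current_pa: np.ndarray  # (n_sweeps, n_samples)
    capacitance_pf: float
    ljp_mv: float = 15.0
    holding_mv: float = -15.0

    def __post_init__(self) -> None:
        self.sweep_times = np.asarray(self.sweep_times, dtype=float)
        self.command_voltage_mv = np.asarray(self.command_voltage_mv, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.current_pa.shape != (
            len(self.sweep_times),
            len(self.command_voltage_mv),
        ):
            raise ValueError("current array must be (n_sweeps, n_samples)")

    @property
    def corrected_voltage_mv(self) -> np.ndarray:
        return self.command_voltage_mv - self.ljp_mv


@dataclass
class CurrentTimeCourse:
    """Per-sweep current at each evaluation potential for one cell."""

    cell_id: str
    sweep_times: np.ndarray  # (n_sweeps,)
    potentials_mv: tuple[float, ...]
    current_pa: np.ndarray  # (n_sweeps, n_potentials)
    capacitance_pf: float
    baseline_subtracted: bool = False

    @property
    def density_pa_pf(self) -> np.ndarray:
        return self.current_pa / self.capacitance_pf

    def at(self, potential: float) -> np.ndarray:
        try:
            j = self.potentials_mv.index(potential)
        except ValueError as err:
            raise KeyError(f"potential {potential} mV not extracted") from err
        return self.current_pa[:, j]


def extract_currents(
    series: RampSweepSeries, potentials_mv: tuple[float, ...] = (-80.0, 80.0)
) -> CurrentTimeCourse:
    """Read each sweep's current at the requested corrected potentials.

    The requested potential refers to the LJP-corrected membrane voltage,
    i.e. the sample is taken where the command voltage equals
    ``potential + ljp_mv``, linearly interpolating between the bracketing
    samples.
    """
    v = series.corrected_voltage_mv
    dv = np.diff(v)
    if np.any(dv <= 0):
        if np.any(dv < 0) and np.any(dv > 0):
            warnings.warn(
                "non-monotonic voltage within ramp segment", stacklevel=2
            )
        order = np.argsort(v, kind="stable")
    else:
        order = slice(None)
    v_sorted = v[order]
    lo, hi = float(v_sorted[0]), float(v_sorted[-1])
    for p in potentials_mv:
        if not lo <= p <= hi:
            raise ValueError(
                f"evaluation potential {p} mV outside corrected ramp span "
                f"[{lo}, {hi}] mV"
            )
    out = np.empty((len(series.sweep_times), len(potentials_mv)))
    for i, iv in enumerate(series.current_pa):
        iv_sorted = iv[order]
        out[i] = np.interp(potentials_mv, v_sorted, iv_sorted)
    return CurrentTimeCourse(
        cell_id=series.cell_id,
        sweep_times=series.sweep_times.copy(),
        potentials_mv=tuple(float(p) for p in potentials_mv),
        current_pa=out,
        capacitance_pf=series.capacitance_pf,
    )


def baseline_subtract_currents(
    tc: CurrentTimeCourse, baseline_window: tuple[float, float]
) -> CurrentTimeCourse:
    """Subtract the per-potential mean over the baseline window."""
    t0, t1 = baseline_window
    sel = (tc.sweep_times >= t0) & (tc.sweep_times <= t1)
    if not np.any(sel):
        raise ValueError("baseline window contains no sweep")
    baseline = tc.current_pa[sel].mean(axis=0)
    return replace(
        tc, current_pa=tc.current_pa - baseline, baseline_subtracted=True
    )


def qc_min_response(
    tc: CurrentTimeCourse,
    agonist_window: tuple[float, float],
    threshold_pa: float = 10.0,
    direction: str = "inward",
    potential_mv: float | None = None,
) -> bool:
    """Minimum-response quality gate on the agonist-evoked current.

    True iff the baseline-subtracted agonist-evoked current exceeds
    ``threshold_pa`` in magnitude in the stated direction (inward =
    negative).  By default the most negative potential is used for inward
    currents and the most positive for outward ones.
    """
    if direction not in ("inward", "outward"):
        raise ValueError("direction must be 'inward' or 'outward'")
    if potential_mv is None:
        potential_mv = (
            min(tc.potentials_mv) if direction == "inward" else max(tc.potentials_mv)
        )
    t0, t1 = agonist_window
    sel = (tc.sweep_times >= t0) & (tc.sweep_times <= t1)
    if not np.any(sel):
        return False
    values = tc.at(potential_mv)[sel]
    if direction == "inward":
        evoked = float(np.min(values))
        return evoked < 0 and abs(evoked) > threshold_pa
    evoked = float(np.max(values))
    return evoked > threshold_pa


def default_evaluation_times(
    tc: CurrentTimeCourse,
    schedule: ApplicationSchedule,
    *,
    steady_state_lag_s: float = 5.0,
    washout_lag_s: float = 2.0,
) -> tuple[float, float, float]:
    """Before/during/after sweep times around the first inhibitor window.

    Defaults: last sweep before inhibitor onset; first sweep at inhibitor
    steady state (at least ``steady_state_lag_s`` after onset, the channel
    block developing in under 5 s); first sweep ``washout_lag_s`` after
    washout.
    """
    inhibitors = schedule.with_role("inhibitor")
    if not inhibitors:
        raise ValueError("schedule contains no inhibitor application")
    inh = inhibitors[0]
    t = tc.sweep_times
    before = t[t < inh.t_start]
    during = t[(t >= inh.t_start + steady_state_lag_s) & (t <= inh.t_end)]
    after = t[t >= inh.t_end + washout_lag_s]
    if len(before) == 0 or len(during) == 0 or len(after) == 0:
        raise ValueError("cannot place before/during/after evaluation sweeps")
    return float(before[-1]), float(during[0]), float(after[0])


def ephys_inhibition(
    tc: CurrentTimeCourse,
    schedule: ApplicationSchedule | None = None,
    *,
    eval_times: tuple[float, float, float] | None = None,
) -> dict[float, float]:
    """Percent inhibition per evaluation potential.

    Evaluation sweeps are taken from ``eval_times`` (before, during, after)
    or derived from the schedule's first inhibitor window.  The inhibition
    formula is applied to the (baseline-subtracted) current at each
    potential; capacitance cancels, so current densities give the same
    result.
    """
    if eval_times is None:
        if schedule is None:
            raise ValueError("either a schedule or explicit eval_times required")
        eval_times = default_evaluation_times(tc, schedule)
    idx = [int(np.argmin(np.abs(tc.sweep_times - t))) for t in eval_times]
    out: dict[float, float] = {}
    for j, p in enumerate(tc.potentials_mv):
        vb, vd, va = (tc.current_pa[i, j] for i in idx)
        out[p] = inhibition(vb, vd, va)
    return out
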