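"""Neuron gating, responder classification and the inhibition statistic.

Cells are accepted as neurons when they respond to capsaicin or to the
high-K+ depolarizing solution.  A cell counts as a responder to a compound
when its baseline-subtracted, smoothed response amplitude reaches the
response threshold (0.1 ratio units by default; 0.05 in experiments where
the agonist response is pharmacologically attenuated).  Inhibition by a
compound applied on top of a repeated agonist is quantified as

    inhibition = 100 * (1 - 2 * V_during / (V_before + V_after))

where the V's are the response amplitudes immediately before, during and
after the inhibitor application.  Averaging the flanking responses corrects
(to first order) for response rundown across repeated agonist applications.
The statistic can be negative when the response grows during the
application, and it saturates at an artefactual 100% when a cell stops
responding altogether (V_during = V_after = 0); that case is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import (
    ApplicationSchedule,
    CellTrace,
    ScheduleEntry,
    baseline_subtract,
    response_amplitude,
    smooth,
)

__all__ = [
    "InhibitionResult",
    "CellClassification",
    "ClassificationParams",
    "inhibition",
    "inhibition_result",
    "gate_neuron",
    "classify_responder",
    "classify_inhibitor_sensitive",
    "subgroup_2x2",
    "classify_population",
]

RESPONSE_THRESHOLD = 0.1  # ratio units
RESPONSE_THRESHOLD_ATTENUATED = 0.05  # ratio units, attenuated-agonist mode
INHIBITION_THRESHOLD = 7.5  # percent


def inhibition(v_before: float, v_during: float, v_after: float) -> float:
    """Percent inhibition from flanking and overlapped response amplitudes.

    Returns NaN when the denominator ``v_before + v_after`` is zero, in
    which case the statistic is undefined.
    """
    denom = v_before + v_after
    if denom == 0:
        return float("nan")
    return 100.0 * (1.0 - 2.0 * v_during / denom)


@dataclass(frozen=True)
class InhibitionResult:
    """Inhibition value plus the two documented degeneracy flags."""

    value: float
    undefined: bool  # V_before + V_after == 0; value is NaN
    full_suppression_artifact: bool  # V_during = V_after = 0 with V_before > 0


def inhibition_result(
    v_before: float, v_during: float, v_after: float
) -> InhibitionResult:
    value = inhibition(v_before, v_during, v_after)
    undefined = (v_before + v_after) == 0
    artifact = v_before > 0 and v_during == 0 and v_after == 0
    return InhibitionResult(value, undefined, artifact)


def gate_neuron(
    caps_amplitude: float | None,
    highk_amplitude: float | None,
    threshold: float = RESPONSE_THRESHOLD,
) -> bool:
    """A cell is a neuron if it responds to capsaicin OR high-K+ solution.

    Cells with neither amplitude available cannot be gated and must be
    excluded from further analysis.
    """
    amps = [a for a in (caps_amplitude, highk_amplitude) if a is not None]
    if not amps:
        raise ValueError("neuron gating needs a capsaicin or high-K+ amplitude")
    return any(np.isfinite(a) and a >= threshold for a in amps)


def classify_responder(
    amplitude: float, threshold: float = RESPONSE_THRESHOLD
) -> bool:
    """Amplitude at or above the response threshold (>= convention)."""
    return bool(np.isfinite(amplitude) and amplitude >= threshold)


def classify_inhibitor_sensitive(
    inhibition_pct: float, threshold: float = INHIBITION_THRESHOLD
) -> bool:
    """Inhibition strictly larger than the threshold (7.5% by default)."""
    return bool(np.isfinite(inhibition_pct) and inhibition_pct > threshold)


@dataclass
class CellClassification:
    """Per-cell boolean labels and the computed inhibition value."""

    cell_id: str
    is_neuron: bool
    responder: dict = field(default_factory=dict)  # compound -> bool
    amplitudes: dict = field(default_factory=dict)  # (compound, k) -> ratio units
    inhibition_pct: float = float("nan")
    inhibitor_sensitive: bool = False
    inhibition_undefined: bool = False
    inhibition_artifact: bool = False
    excluded: bool = False
    exclusion_reason: str = ""
    diameter_um: float | None = None


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds and conditioning parameters for the classification chain."""

    theta_response: float = RESPONSE_THRESHOLD
    theta_inhibition: float = INHIBITION_THRESHOLD
    n_baseline: int = 20
    smooth_window: int = 5
    post_lag_frames: int = 2
    linear_detrend: bool = False  # drift is deliberately not corrected by default


def _flanking_applications(
    schedule: ApplicationSchedule, inhibitor: ScheduleEntry
) -> tuple[ScheduleEntry | None, ScheduleEntry | None, ScheduleEntry | None, str]:
    """Agonist applications before / during / after an inhibitor window."""
    overlapped = [
        e
        for e in schedule.with_role("agonist")
        if e.overlaps(inhibitor)
    ]
    if not overlapped:
        return None, None, None, ""
    during = overlapped[0]
    compound = during.compound
    apps = [e for e in schedule.applications(compound) if e.role == "agonist"]
    idx = apps.index(during)
    before = apps[idx - 1] if idx > 0 else None
    after = apps[idx + 1] if idx + 1 < len(apps) else None
    return before, during, after, compound


def classify_population(
    traces: list[CellTrace],
    schedule: ApplicationSchedule,
    params: ClassificationParams = ClassificationParams(),
    *,
    caps_compound: str = "capsaicin",
    highk_compound: str = "high-K+",
) -> list[CellClassification]:
    """Run the full per-cell classification chain on raw traces.

    For each cell: baseline-subtract and smooth the trace; read the
    response amplitude of every scheduled application; gate neurons on the
    capsaicin / high-K+ responses; classify responders per compound (using
    the first application not overlapped by an inhibitor); compute the
    inhibition statistic from the agonist applications flanking each
    inhibitor window; and flag the documented degenerate cases.
    """
    inhibitors = schedule.with_role("inhibitor")
    flank = _flanking_applications(schedule, inhibitors[0]) if inhibitors else None

    results: list[CellClassification] = []
    for trace in traces:
        cond = smooth(
            baseline_subtract(trace, params.n_baseline), params.smooth_window
        )
        if params.linear_detrend:
            t, r = cond.time, cond.ratio
            ok = np.isfinite(r)
            slope, icept = np.polyfit(t[ok], r[ok], 1)
            cond.ratio = r - (slope * t + icept)

        amplitudes: dict = {}
        for compound in schedule.compounds():
            for k, entry in enumerate(schedule.applications(compound)):
                amplitudes[(compound, k)] = response_amplitude(
                    cond, entry, post_lag_frames=params.post_lag_frames
                )

        def first_clear_amplitude(compound: str) -> float | None:
            """Amplitude of the first application not overlapping an inhibitor."""
            apps = schedule.applications(compound)
            if not apps:
                return None
            for k, entry in enumerate(apps):
                if not any(entry.overlaps(i) for i in inhibitors):
                    return amplitudes[(compound, k)]
            return amplitudes[(compound, 0)]

        caps_amp = first_clear_amplitude(caps_compound)
        highk_amp = first_clear_amplitude(highk_compound)

        cls = CellClassification(
            cell_id=trace.cell_id, is_neuron=False, amplitudes=amplitudes,
            diameter_um=trace.diameter_um,
        )
        try:
            cls.is_neuron = gate_neuron(caps_amp, highk_amp, params.theta_response)
        except ValueError:
            cls.excluded = True
            cls.exclusion_reason = "no capsaicin or high-K+ application"
            results.append(cls)
            continue
        if not cls.is_neuron:
            cls.excluded = True
            cls.exclusion_reason = "failed neuron gate"

        for compound in schedule.compounds():
            amp = first_clear_amplitude(compound)
            if amp is not None:
                cls.responder[compound] = classify_responder(
                    amp, params.theta_response
                )

        if flank is not None:
            before, during, after, agonist = flank
            if before is None or after is None:
                cls.inhibition_undefined = True
            else:
                apps = [
                    e for e in schedule.applications(agonist) if e.role == "agonist"
                ]
                res = inhibition_result(
                    amplitudes[(agonist, apps.index(before))],
                    amplitudes[(agonist, apps.index(during))],
                    amplitudes[(agonist, apps.index(after))],
                )
                cls.inhibition_pct = res.value
                cls.inhibition_undefined = res.undefined
                cls.inhibition_artifact = res.full_suppression_artifact
                cls.inhibitor_sensitive = (
                    cls.responder.get(agonist, False)
                    and classify_inhibitor_sensitive(
                        res.value, params.theta_inhibition
                    )
                )
        results.append(cls)
    return results


def subgroup_2x2(
    classifications: list[CellClassification],
    *,
    agonist_compound: str = "PS",
    caps_compound: str = "capsaicin",
) -> tuple[dict, pd.DataFrame]:
    """Partition agonist-sensitive neurons by capsaicin and inhibitor status.

    Returns the four cell-id sets and a 2x2 count table whose entries sum
    to the number of agonist-sensitive neurons.
    """
    groups: dict[tuple[bool, bool], list[str]] = {
        (True, True): [], (True, False): [], (False, True): [], (False, False): []
    }
    for c in classifications:
        if c.excluded or not c.is_neuron:
            continue
        if not c.responder.get(agonist_compound, False):
            continue
        key = (c.responder.get(caps_compound, False), c.inhibitor_sensitive)
        groups[key].append(c.cell_id)
    table = pd.DataFrame(
        {
            "inhibitor_sensitive": [
                len(groups[(True, True)]), len(groups[(False, True)])
            ],
            "inhibitor_insensitive": [
                len(groups[(True, False)]), len(groups[(False, False)])
            ],
        },
        index=pd.Index(["caps_sensitive", "caps_insensitive"], name="subgroup"),
    )
    named = {
        "caps+/inh+": groups[(True, True)],
        "caps+/inh-": groups[(True, False)],
        "caps-/inh+": groups[(False, True)],
        "caps-/inh-": groups[(False, False)],
    }
    return named, table
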