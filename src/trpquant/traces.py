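"""Per-cell ratio-trace conditioning and window statistics.

A recording yields, for every cell, a time series of the Fura-2 340/380 nm
excitation ratio sampled on a uniform grid (one ratio point every 5 s by
default).  Quantification proceeds in three steps: the mean of the first 20
points (the first 100 s) is subtracted as baseline, the trace is smoothed
with a centred running window of five values, and response amplitudes are
read as the maximum of the conditioned trace inside an application window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CellTrace",
    "ScheduleEntry",
    "ApplicationSchedule",
    "baseline_subtract",
    "smooth",
    "window_stat",
    "response_amplitude",
]

Role = Literal["agonist", "inhibitor", "depolarization", "vehicle"]


@dataclass(frozen=True)
class ScheduleEntry:
    """One compound-application window on the shared recording time axis."""

    compound: str
    concentration: str
    t_start: float
    t_end: float
    role: Role

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"application window for {self.compound!r} must satisfy "
                f"t_start < t_end, got [{self.t_start}, {self.t_end}]"
            )
        if self.role not in ("agonist", "inhibitor", "depolarization", "vehicle"):
            raise ValueError(f"unknown role {self.role!r}")

    def overlaps(self, other: "ScheduleEntry") -> bool:
        return self.t_start < other.t_end and other.t_start < self.t_end

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass(frozen=True)
class ApplicationSchedule:
    """Ordered list of compound applications superfused during a recording."""

    entries: tuple[ScheduleEntry, ...]

    def __init__(self, entries: Sequence[ScheduleEntry]):
        object.__setattr__(
            self, "entries", tuple(sorted(entries, key=lambda e: e.t_start))
        )
        self._validate()

    def _validate(self) -> None:
        # Repeated applications of one compound must not overlap; an
        # overlap would make the before/during/after bookkeeping ambiguous.
        by_compound: dict[str, list[ScheduleEntry]] = {}
        for e in self.entries:
            by_compound.setdefault((e.compound, e.role), []).append(e)
        for (compound, role), apps in by_compound.items():
            for a, b in zip(apps, apps[1:]):
                if a.overlaps(b):
                    raise ValueError(
                        f"overlapping {role} windows for {compound!r}: "
                        f"{a.window} and {b.window}"
                    )

    def applications(self, compound: str) -> list[ScheduleEntry]:
        """All applications of ``compound``, in chronological order."""
        return [e for e in self.entries if e.compound == compound]

    def with_role(self, role: Role) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.role == role]

    @property
    def t_end(self) -> float:
        return max(e.t_end for e in self.entries)

    def compounds(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.compound not in seen:
                seen.append(e.compound)
        return seen


@dataclass
class CellTrace:
    """One cell's ratio time series plus metadata.

    ``ratio`` may contain NaN for frames where no valid ratio could be
    computed (e.g. a fully masked ROI); all statistics ignore missing
    points.
    """

    cell_id: str
    time: np.ndarray
    ratio: np.ndarray
    recording_id: str = ""
    diameter_um: float | None = None
    baseline: float | None = None  # set by baseline_subtract
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.ratio.shape:
            raise ValueError("time and ratio must be 1-D arrays of equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must be uniformly spaced")

    @property
    def frame_interval(self) -> float:
        if len(self.time) < 2:
            raise ValueError("frame interval undefined for a single-frame trace")
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


def baseline_subtract(trace: CellTrace, n_baseline: int = 20) -> CellTrace:
    """Subtract the mean of the first ``n_baseline`` points from the trace.

    With the default 20 points at 5 s spacing the baseline window covers the
    first 100 s of the experiment.  The baseline value is retained on the
    returned trace's ``baseline`` attribute.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if len(trace) <= n_baseline:
        raise ValueError(
            f"trace of length {len(trace)} too short for a "
            f"{n_baseline}-point baseline"
        )
    baseline = float(np.nanmean(trace.ratio[:n_baseline]))
    return replace(trace, ratio=trace.ratio - baseline, baseline=baseline)


def smooth(trace: CellTrace, window: int = 5) -> CellTrace:
    """Centred running-window average of the stated (odd) width.

    At the edges the window shrinks symmetrically to the available points,
    so output length equals input length.  Missing (NaN) points are
    excluded from each window mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if len(trace) < window:
        raise ValueError("trace shorter than smoothing window")
    if window == 1:
        return replace(trace, ratio=trace.ratio.copy())
    half = window // 2
    x = trace.ratio
    valid = np.isfinite(x)
    vals = np.where(valid, x, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    # shrink the window symmetrically at the edges
    n = len(x)
    for i in range(half):
        w = 2 * i + 1
        lo, hi = 0, w
        sums[i] = np.sum(vals[lo:hi])
        counts[i] = np.sum(valid[lo:hi])
        sums[n - 1 - i] = np.sum(vals[n - w :])
        counts[n - 1 - i] = np.sum(valid[n - w :])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    return replace(trace, ratio=out)


def window_stat(
    trace: CellTrace,
    window: tuple[float, float],
    stat: Literal["max", "mean", "min"] = "max",
    *,
    missing_warn_fraction: float = 0.5,
) -> float:
    """Maximum, average or minimum of the trace inside a time window.

    The window is inclusive at both ends; missing values are excluded.
    Returns NaN when every sample in the window is missing.
    """
    t0, t1 = window
    sel = (trace.time >= t0) & (trace.time <= t1)
    if not np.any(sel):
        raise ValueError(f"window [{t0}, {t1}] overlaps no sample")
    values = trace.ratio[sel]
    finite = np.isfinite(values)
    if not np.any(finite):
        return float("nan")
    funcs = {"max": np.max, "mean": np.mean, "min": np.min}
    if stat not in funcs:
        raise ValueError(f"unknown statistic {stat!r}")
    return float(funcs[stat](values[finite]))


def response_amplitude(
    trace: CellTrace,
    entry: ScheduleEntry,
    *,
    post_lag_frames: int = 2,
) -> float:
    """Windowed maximum of a conditioned trace over an application window.

    The trace must already be baseline-subtracted and smoothed.  The window
    is extended past the end of the application by ``post_lag_frames``
    frames so that peaks developing just after washout onset are captured.
    """
    lag = post_lag_frames * trace.frame_interval if len(trace) > 1 else 0.0
    return window_stat(trace, (entry.t_start, entry.t_end + lag), "max")
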