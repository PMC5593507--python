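import numpy as np
import pytest

from trpquant import (
    ApplicationSchedule,
    CellTrace,
    ScheduleEntry,
    default_schedule,
)


@pytest.fixture
def schedule() -> ApplicationSchedule:
    """Three-PS protocol with DAMGO over the second application."""
    return default_schedule()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trace(ratio, dt=5.0, cell_id="c0", **kw) -> CellTrace:
    ratio = np.asarray(ratio, dtype=float)
    return CellTrace(
        cell_id=cell_id, time=np.arange(len(ratio)) * dt, ratio=ratio, **kw
    )


@pytest.fixture
def flat_trace() -> CellTrace:
    return make_trace(np.full(80, 0.5))


@pytest.fixture
def single_agonist_schedule() -> ApplicationSchedule:
    return ApplicationSchedule(
        [
            ScheduleEntry("PS", "25 uM", 120.0, 180.0, "agonist"),
            ScheduleEntry("high-K+", "39 mM", 300.0, 330.0, "depolarization"),
        ]
    )
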