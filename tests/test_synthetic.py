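"""Generator invariants: determinism, label consistency, geometry, ramps."""

import numpy as np
import pytest

from trpquant import (
    CellEllipse,
    FieldGeometry,
    RampSimParams,
    SyntheticPopulationConfig,
    classify_population,
    extract_currents,
    generate_population,
    generate_ramp_recording,
    render_image_stacks,
)
from trpquant.synthetic import write_dataset


class TestGeneratePopulation:
    def test_identical_config_and_seed_bitwise_identical(self, schedule):
        config = SyntheticPopulationConfig(n_cells=30, seed=42)
        t1, l1 = generate_population(config, schedule)
        t2, l2 = generate_population(config, schedule)
        from dataclasses import asdict

        np.testing.assert_equal(  # NaN-tolerant field-wise equality
            [asdict(l) for l in l1], [asdict(l) for l in l2]
        )
        for a, b in zip(t1, t2):
            assert np.array_equal(a.ratio, b.ratio)
            assert np.array_equal(a.time, b.time)

    def test_different_seed_different_noise(self, schedule):
        a, _ = generate_population(
            SyntheticPopulationConfig(n_cells=5, seed=1), schedule
        )
        b, _ = generate_population(
            SyntheticPopulationConfig(n_cells=5, seed=2), schedule
        )
        assert not np.array_equal(a[0].ratio, b[0].ratio)

    def test_noise_free_inhibition_exactly_half(self, schedule):
        """inhibition_depth 0.5 with rundown 1 gives V_during = 0.5 V_before
        = 0.5 V_after, hence exactly 50% by symmetry."""
        config = SyntheticPopulationConfig(
            n_cells=60, noise_sd=0.0, drift_slope=0.0, inhibition_depth=0.5,
            rundown_factor=1.0, ps_amplitude_sd=0.0, caps_amplitude_sd=0.0,
            seed=9,
        )
        traces, labels = generate_population(config, schedule)
        cls = classify_population(traces, schedule)
        by_id = {c.cell_id: c for c in cls}
        n_checked = 0
        for l in labels:
            if l.ps_sensitive and l.inhibitor_sensitive:
                assert by_id[l.cell_id].inhibition_pct == pytest.approx(50.0)
                assert l.true_inhibition == pytest.approx(50.0)
                n_checked += 1
        assert n_checked > 0

    def test_ps_fraction_within_3_binomial_sd(self, schedule):
        config = SyntheticPopulationConfig(
            n_cells=1000, frac_ps_sensitive=0.17, seed=123
        )
        _, labels = generate_population(config, schedule)
        n = sum(l.ps_sensitive for l in labels)
        sd = np.sqrt(1000 * 0.17 * 0.83)
        assert abs(n - 170) <= 3 * sd

    def test_no_neurons_all_fail_gate(self, schedule):
        config = SyntheticPopulationConfig(n_cells=25, frac_neuron=0.0, seed=3)
        traces, labels = generate_population(config, schedule)
        assert not any(l.is_neuron for l in labels)
        cls = classify_population(traces, schedule)
        assert not any(c.is_neuron for c in cls)

    def test_labels_consistent_with_signals(self, schedule):
        """A PS-insensitive cell carries zero PS-evoked signal before noise."""
        config = SyntheticPopulationConfig(
            n_cells=120, noise_sd=0.0, drift_slope=0.0, seed=8
        )
        traces, labels = generate_population(config, schedule)
        ps1 = schedule.applications("PS")[0]
        for tr, l in zip(traces, labels):
            sel = (tr.time >= ps1.t_start) & (tr.time <= ps1.t_end)
            evoked = tr.ratio[sel].max() - tr.ratio[0]
            if l.ps_sensitive:
                assert evoked > 0.1
            else:
                assert evoked == pytest.approx(0.0, abs=1e-12)
            assert not (l.ps_sensitive and not l.is_neuron)

    def test_rundown_scales_repeated_applications(self, schedule):
        config = SyntheticPopulationConfig(
            n_cells=40, noise_sd=0.0, drift_slope=0.0, rundown_factor=0.8,
            ps_amplitude_sd=0.0, inhibition_depth=0.0,
            frac_inhibitor_sensitive_given_ps=1.0,
            frac_inhibitor_sensitive_given_ps_caps=1.0,
            frac_inhibitor_sensitive_given_ps_nocaps=1.0,
            seed=4,
        )
        traces, labels = generate_population(config, schedule)
        apps = schedule.applications("PS")
        tr = next(
            t for t, l in zip(traces, labels) if l.ps_sensitive
        )
        amps = []
        for e in apps:
            sel = (tr.time >= e.t_start) & (tr.time <= e.t_end)
            amps.append(tr.ratio[sel].max() - tr.ratio[0])
        assert amps[1] / amps[0] == pytest.approx(0.8, rel=1e-9)
        assert amps[2] / amps[0] == pytest.approx(0.64, rel=1e-9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SyntheticPopulationConfig(frac_ps_sensitive=1.2)
        with pytest.raises(ValueError, match="rundown"):
            SyntheticPopulationConfig(rundown_factor=0.0)

    def test_overlapping_same_compound_windows_rejected(self):
        from trpquant import ApplicationSchedule, ScheduleEntry

        with pytest.raises(ValueError, match="overlapping"):
            ApplicationSchedule(
                [
                    ScheduleEntry("PS", "25 uM", 100.0, 200.0, "agonist"),
                    ScheduleEntry("PS", "25 uM", 150.0, 250.0, "agonist"),
                ]
            )

    def test_write_dataset_round_trips(self, tmp_path, schedule):
        from trpquant.pipeline import load_traces_csv

        config = SyntheticPopulationConfig(n_cells=8, seed=2)
        paths = write_dataset(tmp_path, config, schedule)
        traces, _ = generate_population(config, schedule)
        loaded = load_traces_csv(paths["traces"])
        assert len(loaded) == 8
        orig = {t.cell_id: t for t in traces}
        for tr in loaded:
            assert np.allclose(tr.ratio, orig[tr.cell_id].ratio)


class TestRenderImageStacks:
    def test_constant_ratio_renders_identity(self, schedule):
        from trpquant import compute_ratio_stack, extract_roi_trace
        from trpquant.imaging import RoiDefinition

        from .conftest import make_trace

        tr = make_trace(np.ones(10))
        geom = [CellEllipse("r0", 40.0, 40.0, 8.0, 8.0)]
        s340, s380, roi_table = render_image_stacks([tr], geom, FieldGeometry(96, 96))
        rstack = compute_ratio_stack(s340, s380, 100.0, 10.0)
        roi = RoiDefinition("r0", 40.0, 40.0, 8.0, 8.0)
        out = extract_roi_trace(rstack, roi)
        assert np.allclose(out.ratio, 1.0, atol=1e-4)

    def test_two_cells_round_trip_within_quantization(self):
        from trpquant import compute_ratio_stack, extract_roi_trace
        from trpquant.imaging import RoiDefinition

        from .conftest import make_trace

        t1 = make_trace(np.full(12, 0.5), cell_id="a")
        t2 = make_trace(np.full(12, 2.0), cell_id="b")
        geom = [
            CellEllipse("a", 30.0, 30.0, 7.0, 5.0, 0.3),
            CellEllipse("b", 80.0, 70.0, 9.0, 6.0, 1.0),
        ]
        s340, s380, _ = render_image_stacks([t1, t2], geom, FieldGeometry(128, 128))
        rstack = compute_ratio_stack(s340, s380, 100.0, 10.0)
        for tr, e in zip((t1, t2), geom):
            roi = RoiDefinition(
                e.roi_id, e.center_x_px, e.center_y_px,
                e.semi_axis_a_px, e.semi_axis_b_px, e.orientation_rad,
            )
            out = extract_roi_trace(rstack, roi)
            assert np.allclose(out.ratio, tr.ratio, rtol=0.01)

    def test_overlapping_ellipses_rejected(self):
        from .conftest import make_trace

        tr = make_trace(np.ones(5))
        geom = [
            CellEllipse("a", 40.0, 40.0, 10.0, 10.0),
            CellEllipse("b", 45.0, 40.0, 10.0, 10.0),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            render_image_stacks([tr, tr], geom, FieldGeometry(96, 96))

    def test_ellipse_outside_field_rejected(self):
        from .conftest import make_trace

        tr = make_trace(np.ones(5))
        geom = [CellEllipse("a", 5.0, 5.0, 10.0, 10.0)]
        with pytest.raises(ValueError, match="fit inside"):
            render_image_stacks([tr], geom, FieldGeometry(96, 96))


class TestGenerateRamp:
    def test_noise_free_ninety_percent_inhibition(self, rng):
        from trpquant import baseline_subtract_currents, ephys_inhibition

        params = RampSimParams(
            rectification="outward", inhibitor_scale=0.1, noise_pa=0.0
        )
        series = generate_ramp_recording(params)
        tc = extract_currents(series, (-80.0, 80.0))
        tc = baseline_subtract_currents(tc, (0.0, 20.0))
        inh = ephys_inhibition(tc, eval_times=(60.0, 90.0, 140.0))
        assert inh[80.0] == pytest.approx(90.0, abs=1e-9)
        assert inh[-80.0] == pytest.approx(90.0, abs=1e-9)

    def test_zero_conductance_gives_zero_currents(self):
        params = RampSimParams(conductance_ns=0.0, noise_pa=0.0)
        series = generate_ramp_recording(params)
        tc = extract_currents(series, (-80.0, 80.0))
        assert np.allclose(tc.current_pa, 0.0)

    def test_ohmic_conductance_symmetric_about_reversal(self):
        """For I = g(V - Vrev) with Vrev = 0, I(+80)/I(-80) = -1 exactly."""
        params = RampSimParams(
            rectification="ohmic", reversal_mv=0.0, noise_pa=0.0,
            inhibitor_windows=(),
        )
        series = generate_ramp_recording(params)
        tc = extract_currents(series, (-80.0, 80.0))
        active = np.abs(tc.at(80.0)) > 0
        ratio = tc.at(80.0)[active] / tc.at(-80.0)[active]
        assert np.allclose(ratio, -1.0)

    def test_determinism(self):
        params = RampSimParams(noise_pa=2.0, seed=77)
        a = generate_ramp_recording(params)
        b = generate_ramp_recording(params)
        assert np.array_equal(a.current_pa, b.current_pa)
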