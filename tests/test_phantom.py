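import numpy as np
import pytest

from cardio5d.errors import GeometryError, ParameterError
from cardio5d.phantom import (
    DoseGridSpec,
    Ellipsoid,
    MotionModel,
    PhantomSpec,
    Sphere,
    Tube,
    default_phantom_spec,
    generate_cardiac_triggers,
    generate_respiratory_waveform,
    render_dose,
    render_mask,
    render_phase_grid,
    simulate_cohort,
)


class TestRespiratoryWaveform:
    def test_noiseless_waveform_is_exactly_periodic(self):
        w = generate_respiratory_waveform(20.0, dt_s=0.05, period_s=4.0)
        n_period = int(round(4.0 / 0.05))
        np.testing.assert_allclose(
            w.amplitudes[: -n_period], w.amplitudes[n_period:], atol=1e-12
        )

    def test_same_seed_reproduces_samples(self):
        w1 = generate_respiratory_waveform(30.0, noise_sd=0.1, seed=42)
        w2 = generate_respiratory_waveform(30.0, noise_sd=0.1, seed=42)
        np.testing.assert_array_equal(w1.amplitudes, w2.amplitudes)

    def test_sample_mean_equals_midline_over_whole_periods(self):
        # closed form: the mean of a sinusoid sampled uniformly over whole
        # periods is its midline
        w = generate_respiratory_waveform(40.0, dt_s=0.02, period_s=4.0, midline=1.7)
        whole = w.amplitudes[:-1]  # drop the endpoint duplicating phase 0
        assert abs(whole.mean() - 1.7) < 1e-9

    def test_maxima_at_end_inhale(self):
        w = generate_respiratory_waveform(8.0, dt_s=0.01, period_s=4.0)
        # peak of the first cycle sits mid-period (end-inhale)
        assert abs(w.times[np.argmax(w.amplitudes[:400])] - 2.0) < 0.02

    def test_drift_is_linear(self):
        w0 = generate_respiratory_waveform(20.0, dt_s=0.05, drift_rate=0.0)
        w1 = generate_respiratory_waveform(20.0, dt_s=0.05, drift_rate=0.1)
        np.testing.assert_allclose(w1.amplitudes - w0.amplitudes, 0.1 * w0.times, atol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"period_s": 0.0},
            {"period_s": -2.0},
            {"dt_s": 0.0},
            {"dt_s": 0.5, "period_s": 4.0},  # step >= period/10
            {"duration_s": -1.0},
        ],
    )
    def test_parameter_errors(self, kwargs):
        params = {"duration_s": 30.0}
        params.update(kwargs)
        with pytest.raises(ParameterError):
            generate_respiratory_waveform(**params)


class TestCardiacTriggers:
    def test_jitter_free_triggers_at_integer_seconds(self):
        tr = generate_cardiac_triggers(60.0, mean_rr_s=1.0)
        assert len(tr.trigger_times) == 61
        np.testing.assert_allclose(tr.trigger_times, np.arange(61.0), atol=1e-12)

    def test_jitter_free_rr_intervals_exact(self):
        tr = generate_cardiac_triggers(10.0, mean_rr_s=0.8)
        np.testing.assert_allclose(np.diff(tr.trigger_times), 0.8, atol=1e-12)

    def test_jitter_sd_recovered_monte_carlo(self):
        # Monte-Carlo check of the stated noise model: sample SD of 1000+
        # intervals within 20% of the injected 0.05 s
        tr = generate_cardiac_triggers(1001.0, mean_rr_s=1.0, rr_jitter_sd_s=0.05, seed=7)
        sd = np.diff(tr.trigger_times).std(ddof=1)
        assert abs(sd - 0.05) < 0.2 * 0.05

    def test_covers_duration(self):
        tr = generate_cardiac_triggers(45.0, mean_rr_s=0.9, rr_jitter_sd_s=0.02, seed=1)
        assert tr.trigger_times[0] == 0.0
        assert tr.trigger_times[-1] >= 45.0

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            generate_cardiac_triggers(0.5, mean_rr_s=1.0)
        with pytest.raises(ParameterError):
            generate_cardiac_triggers(10.0, mean_rr_s=0.0)


class TestRenderMask:
    def setup_method(self):
        self.spec = PhantomSpec(
            substructures={"S": Sphere(center=(37.44, 37.44, 37.44), radius=10.0)},
            grid_shape=(48, 48, 48),
            spacing=(1.56, 1.56, 1.56),
        )

    def test_sphere_volume_close_to_analytic(self):
        mask = render_mask(self.spec, "S")
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert abs(mask.volume_mm3 - analytic) / analytic < 0.05

    def test_one_voxel_displacement_is_exact_lattice_shift(self):
        m0 = render_mask(self.spec, "S")
        m1 = render_mask(self.spec, "S", displacement=(0.0, 0.0, 1.56))
        np.testing.assert_array_equal(m1.data[:, :, 1:], m0.data[:, :, :-1])
        assert m1.n_voxels == m0.n_voxels

    def test_volume_invariant_under_translation(self):
        # voxel-center rasterization keeps the count within the quantization
        # band (a few percent of the surface shell) for sub-voxel shifts
        m0 = render_mask(self.spec, "S")
        for d in [(0.7, -0.4, 0.9), (0.78, 0.78, 0.78), (0.5, 0.1, 0.2)]:
            m1 = render_mask(self.spec, "S", displacement=d)
            assert abs(m1.n_voxels - m0.n_voxels) / m0.n_voxels < 0.05

    def test_zero_radius_is_geometry_error(self):
        with pytest.raises(GeometryError):
            Sphere(center=(0, 0, 0), radius=0.0)
        with pytest.raises(GeometryError):
            Tube(points=((0, 0, 0), (5, 0, 0)), radius=0.0)
        with pytest.raises(GeometryError):
            Ellipsoid(center=(0, 0, 0), semi_axes=(1.0, 0.0, 1.0))

    def test_out_of_bounds_displacement_raises(self):
        with pytest.raises(GeometryError):
            render_mask(self.spec, "S", displacement=(40.0, 0.0, 0.0))

    def test_unknown_substructure(self):
        with pytest.raises(ParameterError):
            render_mask(self.spec, "nope")

    def test_tube_contains_axis_voxels(self):
        spec = PhantomSpec(
            substructures={"T": Tube(points=((10.0, 24.0, 24.0), (38.0, 24.0, 24.0)), radius=3.0)},
            grid_shape=(48, 48, 48),
            spacing=(1.0, 1.0, 1.0),
        )
        mask = render_mask(spec, "T")
        assert mask.data[24, 24, 24]
        assert not mask.data[24, 35, 24]


class TestMotionModel:
    def test_loop_closes_at_respiratory_extremes(self):
        m = MotionModel(resp_amp=(0, 1, -4), hysteresis_mm=6.0)
        # EE and EI displacements carry no limb term at all
        for state in ("EE", "EI"):
            d = m.displacement("ED", state)
            base = np.asarray(m.resp_amp) * (0.0 if state == "EE" else 1.0)
            np.testing.assert_allclose(d, base, atol=1e-9)

    def test_zero_hysteresis_makes_limbs_identical(self):
        m = MotionModel(resp_amp=(0, 1, -4), hysteresis_mm=0.0)
        np.testing.assert_allclose(
            m.displacement("ES", "AEx"), m.displacement("ES", "AIn"), atol=1e-12
        )

    def test_limb_separation_equals_hysteresis(self):
        m = MotionModel(resp_amp=(0, 1, -4), hysteresis_mm=5.0)
        gap = m.displacement("ED", "AIn") - m.displacement("ED", "AEx")
        assert abs(np.linalg.norm(gap) - 5.0) < 1e-12

    def test_perp_axis_orthogonal_to_stroke(self):
        m = MotionModel(resp_amp=(0.3, 1.0, -4.0), hysteresis_mm=1.0)
        assert abs(m.perp_axis() @ np.asarray(m.resp_amp)) < 1e-9

    def test_negative_hysteresis_rejected(self):
        with pytest.raises(ParameterError):
            MotionModel(hysteresis_mm=-1.0)


class TestRenderPhaseGrid:
    def _spec(self):
        return PhantomSpec(
            substructures={"S": Sphere(center=(37.44, 37.44, 37.44), radius=10.0)},
            grid_shape=(48, 48, 48),
            spacing=(1.56, 1.56, 1.56),
        )

    def test_zero_hysteresis_gives_identical_limb_masks(self):
        grid, _ = render_phase_grid(
            self._spec(), MotionModel(cardiac_amp=(1, 0, -2), resp_amp=(0, 0, -4))
        )
        for c in ("ED", "ES"):
            np.testing.assert_array_equal(
                grid.get("S", c, "AEx").data, grid.get("S", c, "AIn").data
            )

    def test_zero_cardiac_amp_gives_identical_ed_es(self):
        grid, _ = render_phase_grid(
            self._spec(), MotionModel(resp_amp=(0, 1, -4), hysteresis_mm=2.0)
        )
        for r in ("EE", "AEx", "AIn", "EI"):
            np.testing.assert_array_equal(
                grid.get("S", "ED", r).data, grid.get("S", "ES", r).data
            )

    def test_ground_truth_si_matches_injection(self):
        # injected EE->EI SI stroke is recorded exactly for every cardiac phase
        grid, truth = render_phase_grid(
            self._spec(), MotionModel(resp_amp=(0, 0, -6.0))
        )
        for c in ("ED", "ES"):
            ee = truth.query("cardiac_phase == @c and resp_state == 'EE'")["si_mm"].item()
            ei = truth.query("cardiac_phase == @c and resp_state == 'EI'")["si_mm"].item()
            assert ei - ee == pytest.approx(-6.0, abs=1e-12)

    def test_grid_has_full_phase_product(self):
        grid, truth = render_phase_grid(self._spec(), MotionModel())
        assert len(grid) == 8
        assert len(truth) == 8
        assert grid.is_complete("S")


class TestRenderDose:
    def test_uniform(self):
        dose = render_dose(DoseGridSpec(mode="uniform", level_gy=10.0, grid_shape=(8, 8, 8)))
        np.testing.assert_array_equal(dose.values, 10.0)

    def test_linear_gradient_closed_form(self):
        spec = DoseGridSpec(
            mode="linear_gradient",
            level_gy=30.0,
            gradient_gy_per_mm=(0, 0, 1.0),
            gradient_ref_mm=(0, 0, 10.0),
            grid_shape=(4, 4, 32),
            spacing=(1.0, 1.0, 1.0),
        )
        dose = render_dose(spec)
        assert dose.values[0, 0, 15] == pytest.approx(35.0)  # z0 + 5 mm

    def test_gradient_clipped_at_zero(self):
        spec = DoseGridSpec(
            mode="linear_gradient",
            level_gy=1.0,
            gradient_gy_per_mm=(0, 0, 1.0),
            gradient_ref_mm=(0, 0, 30.0),
            grid_shape=(4, 4, 32),
            spacing=(1.0, 1.0, 1.0),
        )
        assert render_dose(spec).values.min() == 0.0

    def test_gaussian_bounded_by_peak(self):
        dose = render_dose(
            DoseGridSpec(mode="gaussian", peak_gy=60.0, center_mm=(24, 24, 24),
                         width_mm=10.0, grid_shape=(32, 32, 32), spacing=(1.5, 1.5, 1.5))
        )
        assert dose.values.max() <= 60.0
        assert dose.values.min() >= 0.0

    def test_negative_level_rejected(self):
        with pytest.raises(ParameterError):
            render_dose(DoseGridSpec(mode="uniform", level_gy=-1.0))
        with pytest.raises(ParameterError):
            render_dose(DoseGridSpec(mode="unknown"))


class TestSimulateCohort:
    def test_fixed_seed_bit_identical_truth(self):
        spec = default_phantom_spec(grid_shape=(48, 48, 48))
        a = simulate_cohort(2, spec=spec, amp_jitter_sd_mm=0.5, seed=3)
        b = simulate_cohort(2, spec=spec, amp_jitter_sd_mm=0.5, seed=3)
        for (_, ga, ta), (_, gb, tb) in zip(a, b):
            assert ta.equals(tb)
            for (key, ma), (_, mb) in zip(ga, gb):
                np.testing.assert_array_equal(ma.data, mb.data)

    def test_jitter_changes_subjects(self):
        spec = default_phantom_spec(grid_shape=(48, 48, 48))
        cohort = simulate_cohort(2, spec=spec, amp_jitter_sd_mm=1.0, seed=5)
        t1 = cohort[0][2].drop(columns="subject").set_index(
            ["substructure", "cardiac_phase", "resp_state"]
        )
        t2 = cohort[1][2].drop(columns="subject").set_index(
            ["substructure", "cardiac_phase", "resp_state"]
        )
        assert not np.allclose(t1.to_numpy(), t2.to_numpy())

    def test_invalid_n_subjects(self):
        with pytest.raises(ParameterError):
            simulate_cohort(0)
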