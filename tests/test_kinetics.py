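import numpy as np
import pytest
from scipy.integrate import solve_ivp

from myoperf.kinetics import (
    FineCurve,
    FrameAverager,
    KineticParams,
    OneTissueModel,
    fit_1tcm,
    fit_region_set,
    frame_average,
    simulate_tissue_curve,
    write_fit_report_csv,
)
from myoperf.synthetic import InputFunctionParams, feng_input, feng_values
from myoperf.tac import TimeActivityCurve, make_frame_schedule
from myoperf.units import seconds_to_minutes


def constant_input(value=1.0, t_end_min=2.0, step_min=1 / 120):
    t = np.arange(0.0, t_end_min + step_min / 2, step_min)
    return FineCurve(t, np.full_like(t, value))


def ode_oracle(params: KineticParams, input_curve: FineCurve) -> np.ndarray:
    """High-accuracy ODE integration of the 1TCM, independent of the
    recursive convolution implementation."""
    t = input_curve.times_min

    def ca(s):
        return np.interp(s, t, input_curve.values)

    def rhs(s, y):
        return [params.K1 * ca(s) - params.k2 * y[0]]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, rtol=1e-10, atol=1e-12,
                    max_step=float(t[1] - t[0]))
    ct = sol.y[0]
    return (1.0 - params.Vb) * ct + params.Vb * input_curve.values


class TestForwardModel:
    def test_constant_infusion_closed_form(self):
        """Ca=1, K1=k2=0.5, Vb=0: C(t) = (K1/k2)(1 - exp(-k2 t))."""
        curve = simulate_tissue_curve(KineticParams(0.5, 0.5, 0.0), constant_input())
        expected = (0.5 / 0.5) * (1.0 - np.exp(-0.5 * curve.times_min))
        assert np.allclose(curve.values, expected, atol=5e-7)
        assert curve.values[-1] == pytest.approx(0.6321, abs=1e-4)

    def test_pure_blood_identity(self):
        ca = constant_input(3.7)
        curve = simulate_tissue_curve(KineticParams(1.3, 0.4, 1.0), ca)
        assert np.array_equal(curve.values, ca.values)

    def test_irreversible_linear_accumulation(self):
        """k2=0 with constant input gives C(t) = K1*t exactly."""
        curve = simulate_tissue_curve(KineticParams(0.3, 0.0, 0.0), constant_input())
        assert np.allclose(curve.values, 0.3 * curve.times_min, rtol=1e-12, atol=1e-14)

    def test_linearity_in_k1(self, bolus_input):
        c1 = simulate_tissue_curve(KineticParams(0.4, 0.8, 0.0), bolus_input)
        c2 = simulate_tissue_curve(KineticParams(0.8, 0.8, 0.0), bolus_input)
        assert np.allclose(c2.values, 2.0 * c1.values, rtol=1e-12)

    def test_higher_k2_never_raises_late_activity(self, bolus_input):
        lo = simulate_tissue_curve(KineticParams(0.9, 0.5, 0.0), bolus_input)
        hi = simulate_tissue_curve(KineticParams(0.9, 1.5, 0.0), bolus_input)
        assert np.all(hi.values <= lo.values + 1e-12)

    def test_matches_ode_oracle_on_random_draws(self, bolus_input):
        """Convolution engine vs high-accuracy ODE integration."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            p = KineticParams(
                rng.uniform(0.1, 3.0), rng.uniform(0.1, 5.0), rng.uniform(0.0, 0.5)
            )
            ours = simulate_tissue_curve(p, bolus_input).values
            ref = ode_oracle(p, bolus_input)
            worst = max(worst, np.max(np.abs(ours - ref)) / np.max(ref))
        assert worst < 1e-4

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError):
            FineCurve(np.array([0.0, 0.1, 0.3]), np.zeros(3))


class TestFrameAverage:
    def test_constant_curve(self, schedule52):
        t = seconds_to_minutes(np.arange(0, 3601) * 0.5)
        tac = frame_average(FineCurve(t, np.full_like(t, 4.2)), schedule52)
        assert np.allclose(tac.values, 4.2, rtol=1e-12)

    def test_linear_ramp_first_minute(self):
        t = np.arange(0.0, 1.0 + 1e-12, 1 / 120)
        sched = make_frame_schedule([(1, 60)])
        tac = frame_average(FineCurve(t, t.copy()), sched)
        assert tac.values[0] == pytest.approx(0.5, rel=1e-12)

    def test_grid_refinement_convergence(self, schedule52):
        """Halving the step changes frame means of a smooth curve by < 1e-6."""

        def smooth(t):
            return np.exp(-t / 5.0) + 0.5 * np.exp(-t / 10.0)

        coarse_t = seconds_to_minutes(np.arange(0, 3601) * 0.5)
        fine_t = seconds_to_minutes(np.arange(0, 7201) * 0.25)
        coarse = frame_average(FineCurve(coarse_t, smooth(coarse_t)), schedule52).values
        fine = frame_average(FineCurve(fine_t, smooth(fine_t)), schedule52).values
        assert np.max(np.abs(coarse - fine) / np.max(fine)) < 1e-6

    def test_schedule_past_curve_rejected(self):
        t = np.arange(0.0, 1.0, 1 / 120)
        with pytest.raises(ValueError):
            frame_average(FineCurve(t, t.copy()), make_frame_schedule([(2, 60)]))

    def test_averager_matrix_matches_general_path(self, schedule52, bolus_input):
        avg = FrameAverager.build(bolus_input.times_min, schedule52)
        general = frame_average(bolus_input, schedule52).values
        assert np.allclose(avg(bolus_input.values), general, rtol=1e-12)


class TestFitting:
    TRUTH = KineticParams(0.6, 1.2, 0.05)

    def test_noiseless_round_trip(self, input_tac, schedule52):
        """Observations produced by the model itself are recovered to
        better than 0.1% relative in every parameter."""
        placeholder = TimeActivityCurve(schedule52, np.zeros(52))
        model = OneTissueModel(placeholder, input_tac)
        obs = TimeActivityCurve(schedule52, model.predict(self.TRUTH))
        res = OneTissueModel(obs, input_tac).fit()
        est = res.params.as_array()
        assert np.all(np.abs(est - self.TRUTH.as_array()) / self.TRUTH.as_array() < 1e-3)
        assert res.converged

    def test_pure_blood_tac(self, input_tac):
        """A tissue TAC identical to the LV input is explained by Vb -> 1
        with a near-zero weighted residual."""
        res = fit_1tcm(input_tac, input_tac)
        assert res.params.Vb == pytest.approx(1.0, abs=1e-3)
        # residual floor set by re-sampling the input from frame values
        assert np.sqrt(res.wrss) < 5e-3 * np.max(input_tac.values)

    def test_all_zero_tissue_gives_zero_k1(self, input_tac, schedule52):
        zero = TimeActivityCurve(schedule52, np.zeros(52))
        res = fit_1tcm(zero, input_tac)
        assert res.params.K1 == pytest.approx(0.0, abs=1e-6)
        assert res.converged

    def test_too_few_frames_rejected(self, input_tac, schedule52):
        tiny = TimeActivityCurve(schedule52, np.ones(52))
        with pytest.raises(ValueError):
            OneTissueModel(tiny, input_tac, fit_window_s=6.0)

    def test_weight_scaling_leaves_argmin_unchanged(self, noiseless_tac_factory, input_tac):
        rng = np.random.default_rng(11)
        tissue = noiseless_tac_factory(0.9, 1.0, 0.12)
        noisy = TimeActivityCurve(
            tissue.schedule, tissue.values + rng.normal(0, 2.0, 52), region_label="r"
        )
        w = tissue.schedule.frame_durations.astype(float)
        r1 = OneTissueModel(noisy, input_tac, weights_mode=w).fit()
        r2 = OneTissueModel(noisy, input_tac, weights_mode=17.3 * w).fit()
        assert np.allclose(r1.params.as_array(), r2.params.as_array(), rtol=1e-6)

    def test_remote_exceeds_infarct_k1_across_seeds(self, bolus_input, schedule52, input_tac):
        """With a 4.3x true contrast, the fitted ordering is preserved in
        every seed of a 20-seed noisy battery."""
        from myoperf.synthetic import StudyDesign
        from myoperf.kinetics import frame_average, simulate_tissue_curve

        design = StudyDesign()
        remote = frame_average(
            simulate_tissue_curve(KineticParams(0.9, 1.0, 0.12), bolus_input), schedule52
        )
        infarct = frame_average(
            simulate_tissue_curve(KineticParams(0.9 / 4.3, 0.25, 0.12), bolus_input), schedule52
        )
        dt_min = seconds_to_minutes(schedule52.frame_durations)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fits = []
            for tac in (remote, infarct):
                sd = design.noise_alpha * np.sqrt(
                    np.maximum(tac.values, design.c_floor) / dt_min
                )
                noisy = TimeActivityCurve(schedule52, tac.values + rng.normal(0, 1, 52) * sd)
                fits.append(fit_1tcm(noisy, input_tac).params.K1)
            assert fits[0] > fits[1]

    def test_region_set_determinism_and_isolation(self, noiseless_tac_factory, input_tac):
        a = noiseless_tac_factory(0.9, 1.0, 0.1, label="a")
        table = {"a": a, "b": a, "bad": TimeActivityCurve(a.schedule, np.ones(52))}
        out = fit_region_set(table, input_tac, tracer_mode="ga68-dota")
        assert np.array_equal(out["a"].params.as_array(), out["b"].params.as_array())
        assert out["a"].fit_window_s == 1800.0
        assert not isinstance(out["bad"], Exception)  # constant TAC still fits
        assert fit_region_set({}, input_tac) == {}

    def test_acetate_mode_uses_short_window(self, noiseless_tac_factory, input_tac):
        tissue = noiseless_tac_factory(0.9, 0.5, 0.1)
        out = fit_region_set({"s": tissue}, input_tac, tracer_mode="c11-acetate")
        assert out["s"].fit_window_s == 600.0
        assert out["s"].n_frames_used == 48

    def test_summary_and_report(self, noiseless_tac_factory, input_tac, tmp_path):
        res = fit_1tcm(noiseless_tac_factory(0.6, 1.2, 0.05, label="seg01"), input_tac)
        text = res.summary()
        assert "K1" in text and "converged" in text
        write_fit_report_csv(tmp_path / "fits.csv", {"seg01": res}, tracer="ga68-dota")
        header, row = (tmp_path / "fits.csv").read_text().strip().splitlines()
        assert header.startswith("region,tracer,K1,k2,Vb")
        assert row.startswith("seg01,ga68-dota,")
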