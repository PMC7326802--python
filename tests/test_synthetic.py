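import numpy as np
import pytest

from myoperf.kinetics import simulate_tissue_curve
from myoperf.synthetic import (
    TRACER_ACETATE,
    TRACER_DOTA,
    InputFunctionParams,
    StudyDesign,
    default_schedule,
    feng_input,
    feng_values,
    make_ground_truth,
    simulate_autorad,
    simulate_study,
    write_study,
)
from myoperf.units import seconds_to_minutes


class TestFengInput:
    def test_zero_at_and_before_arrival(self):
        p = InputFunctionParams(tau=0.1)
        t = np.array([0.0, 0.05, 0.1])
        assert np.all(feng_values(p, t) == 0.0)

    def test_peak_location_without_recirculation(self):
        """With A2 = A3 = 0 the curve is A1 (t-tau) e^{-l1 (t-tau)},
        peaking at tau + 1/l1."""
        p = InputFunctionParams(A2=1e-9, A3=1e-10, lambda1=6.0, tau=0.1)
        t = np.arange(0, 2.0, 1e-4)
        curve = feng_input(p, t)
        t_peak = t[np.argmax(curve.values)]
        assert t_peak == pytest.approx(0.1 + 1.0 / 6.0, abs=1e-3)

    def test_decays_to_zero(self):
        p = InputFunctionParams()
        assert feng_values(p, np.array([1e4])) == pytest.approx(0.0, abs=1e-6)

    def test_default_peaks_within_20_seconds_and_is_nonnegative(self):
        t = seconds_to_minutes(np.arange(0, 3601) * 0.5)
        curve = feng_input(InputFunctionParams(), t)
        assert seconds_to_minutes(20.0) > t[np.argmax(curve.values)]
        assert np.all(curve.values >= 0.0)

    def test_eigenrate_ordering_enforced(self):
        with pytest.raises(ValueError):
            InputFunctionParams(lambda1=1.0, lambda2=2.0, lambda3=0.1)


class TestGroundTruth:
    def test_same_seed_reproduces_study(self):
        a = make_ground_truth(seed=7)
        b = make_ground_truth(seed=7)
        for x, y in zip(a.animals, b.animals):
            assert x.animal_id == y.animal_id
            for tracer in a.design.tracers:
                assert x.params[tracer] == y.params[tracer]
                assert x.injections[tracer] == y.injections[tracer]

    def test_degenerate_distributions_hit_ratio_exactly(self):
        design = StudyDesign(
            n_mi=2,
            n_sham=0,
            remote_k1_sd=0.0,
            segment_rel_sd=0.0,
            k2_rel_sd=0.0,
            k1_ratio_sd={TRACER_ACETATE: 0.0, TRACER_DOTA: 0.0},
        )
        gt = make_ground_truth(design, seed=0)
        for animal in gt.animals:
            seg = animal.params[TRACER_DOTA]
            remote = seg[2].K1
            infarct = seg[1].K1
            assert remote / infarct == pytest.approx(4.3, rel=1e-12)

    def test_sham_is_homogeneous_in_expectation(self):
        design = StudyDesign(n_mi=0, n_sham=1, segment_rel_sd=0.0)
        gt = make_ground_truth(design, seed=3)
        k1s = [p.K1 for p in gt.animals[0].params[TRACER_DOTA].values()]
        assert np.ptp(k1s) == pytest.approx(0.0, abs=1e-12)

    def test_infarct_outside_layout_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth(StudyDesign(n_segments=5, infarct_segments=(9,),
                                          remote_segments=(2,)), seed=0)

    def test_late_crossover_of_infarct_curve(self):
        """The infarct tissue curve peaks lower early but crosses above the
        remote curve late in the scan (delayed washout)."""
        design = StudyDesign(
            n_mi=1, n_sham=0, noise_alpha=0.0,
            remote_k1_sd=0.0, segment_rel_sd=0.0, k2_rel_sd=0.0,
            k1_ratio_sd={TRACER_ACETATE: 0.0, TRACER_DOTA: 0.0},
        )
        gt = make_ground_truth(design, seed=1)
        study = simulate_study(gt)
        block = study.data[gt.animals[0].animal_id][TRACER_DOTA]
        remote = block["segments"][3].values
        infarct = block["segments"][7].values
        sched = block["input"].schedule
        early = sched.frame_ends <= 60.0
        late = sched.frame_starts >= 1500.0
        assert remote[early].max() > infarct[early].max()
        assert infarct[late].mean() > remote[late].mean()


class TestSimulateStudy:
    def test_zero_noise_matches_forward_model(self):
        design = StudyDesign(n_mi=1, n_sham=0, noise_alpha=0.0)
        gt = make_ground_truth(design, seed=2)
        study = simulate_study(gt)
        animal = gt.animals[0]
        block = study.data[animal.animal_id][TRACER_DOTA]
        from myoperf.kinetics import frame_average, input_curve_from_tac
        from myoperf.synthetic import feng_input

        sched = block["input"].schedule
        inj = animal.injections[TRACER_DOTA]
        scale = (inj.injected_activity_mbq / 29.0) * (300.0 / inj.body_weight_g)
        t = seconds_to_minutes(np.arange(0, 3601) * 0.5)
        fine_in = feng_input(design.input_params.scaled(scale), t)
        expected = frame_average(
            simulate_tissue_curve(animal.params[TRACER_DOTA][5], fine_in), sched
        )
        assert np.allclose(block["segments"][5].values, expected.values, rtol=1e-12)

    def test_fixed_seed_reproducible_and_write_deterministic(self, tmp_path):
        design = StudyDesign(n_mi=1, n_sham=1, n_segments=4,
                             infarct_segments=(1,), remote_segments=(3,))
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            write_study(simulate_study(make_ground_truth(design, seed=9)), out)
        for name in sorted(p.name for p in out1.iterdir()):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_acetate_scan_is_truncated_to_ten_minutes(self):
        design = StudyDesign(n_mi=1, n_sham=0)
        study = simulate_study(make_ground_truth(design, seed=0))
        aid = study.ground_truth.animals[0].animal_id
        assert study.data[aid][TRACER_ACETATE]["input"].schedule.total_duration == 600.0
        assert study.data[aid][TRACER_DOTA]["input"].schedule.total_duration == 1800.0

    def test_noise_model_standardised_residuals(self):
        """Realised noise divided by the nominal sd is ~N(0,1), for short
        and long frames alike -- frame duration scales the sd correctly."""
        design = StudyDesign(n_mi=0, n_sham=2)
        gt = make_ground_truth(design, seed=4)
        noisy = simulate_study(gt)
        clean = simulate_study(gt, noise_alpha=0.0)
        zs, durs = [], []
        for animal in gt.animals:
            block_n = noisy.data[animal.animal_id][TRACER_DOTA]
            block_c = clean.data[animal.animal_id][TRACER_DOTA]
            sched = block_n["input"].schedule
            dt_min = seconds_to_minutes(sched.frame_durations)
            for sid in block_n["segments"]:
                resid = block_n["segments"][sid].values - block_c["segments"][sid].values
                sd = design.noise_alpha * np.sqrt(
                    np.maximum(block_c["segments"][sid].values, design.c_floor) / dt_min
                )
                zs.append(resid / sd)
                durs.append(sched.frame_durations)
        z = np.concatenate(zs)
        durations = np.concatenate(durs)
        assert np.std(z) == pytest.approx(1.0, abs=0.05)
        assert np.std(z[durations == 3.0]) == pytest.approx(1.0, abs=0.08)
        assert np.std(z[durations == 300.0]) == pytest.approx(1.0, abs=0.12)

    def test_negative_alpha_rejected(self):
        gt = make_ground_truth(StudyDesign(n_mi=1, n_sham=0), seed=0)
        with pytest.raises(ValueError):
            simulate_study(gt, noise_alpha=-0.1)


class TestSimulateAutorad:
    def test_null_contrast(self):
        img, masks = simulate_autorad(rho=1.0, remote_density=5.0,
                                      background_density=0.0, noise_sd_density=0.0)
        from myoperf.autorad import count_density

        assert count_density(img, masks["infarct"]) == pytest.approx(
            count_density(img, masks["remote"])
        )

    def test_noiseless_contrast_recovered(self):
        from myoperf.autorad import count_density, fold_ratio

        img, masks = simulate_autorad(rho=4.3, remote_density=6.5,
                                      background_density=0.0, noise_sd_density=0.0)
        est = fold_ratio(count_density(img, masks["infarct"]),
                         count_density(img, masks["remote"]))
        assert est == pytest.approx(4.3, rel=1e-12)

    def test_seeded_noise_reproducible(self):
        a, _ = simulate_autorad(noise_sd_density=0.5, seed=11)
        b, _ = simulate_autorad(noise_sd_density=0.5, seed=11)
        c, _ = simulate_autorad(noise_sd_density=0.5, seed=12)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_geometry_that_does_not_fit_rejected(self):
        with pytest.raises(ValueError):
            simulate_autorad(shape=(10, 200))

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_autorad(rho=0.0)
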