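import numpy as np
import pytest

from gaitload import (
    GaitloadError,
    GaitSimParams,
    generate_design,
    generate_pendulum,
    generate_trial,
    stride_from_rotations,
    table3_preset,
)
from gaitload.preprocess import butterworth, integrate, FilterSpec
from gaitload.synthetic import ShankTemplate, apply_effects


class TestTrialGeneration:
    def test_seed_determinism(self):
        p = GaitSimParams(n_cycles=8)
        r1, _ = generate_trial(p, 42)
        r2, _ = generate_trial(p, 42)
        for site in r1.streams:
            assert np.array_equal(r1.streams[site].gyro, r2.streams[site].gyro)
            assert np.array_equal(r1.streams[site].t, r2.streams[site].t)

    def test_zero_lag_waveforms_identical_up_to_scale(self):
        p = GaitSimParams(
            noise_sd_dps=0.0, drift_dps=0.0, cycle_sd_s=0.0, n_cycles=6,
            phase_lag_deg={"coronal": 0.0, "transverse": 0.0, "sagittal": 0.0},
        )
        _, truth = generate_trial(p, 1)
        for plane in ("coronal", "transverse", "sagittal"):
            t6 = truth.displacement[("T6", plane)]
            s1 = truth.displacement[("S1", plane)]
            ratio = p.sway_amplitude_deg[("S1", plane)] / p.sway_amplitude_deg[("T6", plane)]
            assert np.allclose(s1, ratio * t6, atol=1e-9)

    def test_integration_recovers_constructed_displacement(self, clean_trial):
        """Angular velocity is the analytic derivative of the built
        displacement: numerical integration must return it within 0.1 deg."""
        rec, truth = clean_trial
        for site, plane in [("T6", "coronal"), ("S1", "transverse"), ("T6", "sagittal")]:
            stream = rec.streams[site]
            theta = integrate(stream.axis(plane), stream.fs)
            ref = truth.displacement[(site, plane)]
            assert np.max(np.abs(theta - (ref - ref[0]))) < 0.1

    def test_ground_truth_event_counts(self, noisy_trial):
        _, truth = noisy_trial
        n = len(truth.cycle_durations)
        assert len(truth.heel_strikes) == n + 1
        assert len(truth.toe_offs) == n
        hs = truth.heel_strikes
        assert np.all((truth.toe_offs > hs[:-1]) & (truth.toe_offs < hs[1:]))

    def test_peak_to_peak_equals_twice_amplitude(self, clean_trial):
        """Conservation: constructed displacement peak-to-peak is exactly 2x
        the configured sway amplitude in every full cycle."""
        rec, truth = clean_trial
        p = GaitSimParams(noise_sd_dps=0.0, drift_dps=0.0, cycle_sd_s=0.0, n_cycles=10)
        t = rec.streams["T6"].t
        for (site, plane), amp in p.sway_amplitude_deg.items():
            theta = truth.displacement[(site, plane)]
            for k in range(2, 8):
                sel = (t >= truth.heel_strikes[k]) & (t <= truth.heel_strikes[k + 1])
                pp = theta[sel].max() - theta[sel].min()
                assert pp == pytest.approx(2 * amp, rel=0.01)

    def test_invalid_params_rejected(self):
        with pytest.raises(GaitloadError):
            GaitSimParams(n_cycles=0)
        with pytest.raises(GaitloadError):
            GaitSimParams(phase_lag_deg={"coronal": 200.0, "transverse": 0, "sagittal": 0})

    def test_effect_preset_shifts_lags_and_amplitudes(self):
        p = GaitSimParams()
        shifted, applied = apply_effects(p, table3_preset(), ("side", "H"))
        assert shifted.phase_lag_deg["coronal"] == pytest.approx(109.5 + 23.6)
        assert shifted.sway_amplitude_deg[("T6", "coronal")] == pytest.approx(2.8 - 0.9)
        assert applied["mrp"]["coronal"] == 23.6
        # no-load is never offset
        same, applied0 = apply_effects(p, table3_preset(), ("none", "NL"))
        assert same.phase_lag_deg == p.phase_lag_deg
        assert not applied0["mrp"]


class TestShankTemplate:
    def test_event_ordering(self):
        tpl = ShankTemplate()
        assert 0.4 < tpl.phi_to < tpl.phi_ms < 1.0

    def test_zero_mean_over_cycle(self):
        tpl = ShankTemplate()
        grid = np.linspace(0, 1, 10000, endpoint=False)
        assert abs(np.mean(tpl(grid))) < 1e-6

    def test_angle_periodic(self):
        tpl = ShankTemplate()
        assert tpl.angle_unit(0.0) == pytest.approx(0.0, abs=1e-9)
        assert tpl.angle_unit(0.999999) == pytest.approx(0.0, abs=1e-3)


class TestDesigns:
    def test_expt1_manifest_arithmetic(self):
        res = generate_design("expt1", master_seed=0)
        assert len(res["manifest"]) == 144   # 9 participants x 8 conditions x 2
        counts = res["manifest"].groupby("participant_id").size()
        assert (counts == 16).all()
        # ground truth covers at least 7 cycles per trial
        assert all(len(t.cycle_durations) >= 7 for _, t in res["trials"])

    def test_expt1_reduced_cohort(self):
        res = generate_design("expt1", master_seed=0, n_participants=2)
        assert len(res["manifest"]) == 32

    def test_expt2_drop_list(self):
        res = generate_design("expt2", master_seed=0, n_participants=3)
        assert len(res["drop_list"]) == 3
        assert (res["drop_list"]["cycle"] == 6).all()
        assert all(len(t.cycle_durations) >= 11 for _, t in res["trials"])

    def test_expt1_requires_seven_cycles(self):
        with pytest.raises(GaitloadError, match="n_cycles >= 7"):
            generate_design("expt1", base_params=GaitSimParams(n_cycles=5))

    def test_condition_set_per_participant(self):
        res = generate_design("expt1", master_seed=1, n_participants=1)
        m = res["manifest"]
        conds = set(zip(m["carry_mode"], m["load_kg"]))
        expected = {("none", 0.0)} | {
            (mode, load) for mode in ("side", "anterior") for load in (4.5, 9.1, 13.6)
        }
        assert conds == expected

    def test_design_files_round_trip(self, tmp_path):
        from gaitload import read_manifest, read_anthropometry, load_trial

        res = generate_design("expt1", master_seed=5, n_participants=1,
                              out_dir=tmp_path)
        manifest = read_manifest(tmp_path / "manifest.csv")
        assert len(manifest) == 16
        anthro = read_anthropometry(tmp_path / "anthropometry.csv")
        rec = load_trial(manifest.iloc[0])
        orig = res["trials"][0][0]
        assert rec.key == orig.key
        assert np.allclose(rec.streams["T6"].gyro, orig.streams["T6"].gyro, atol=1e-6)
        assert "P01" in anthro


class TestPendulum:
    def test_integrate_filter_pipeline_rmse_below_one_degree(self):
        """Gyroscope-derived displacement vs the simulated oracle, both
        passed through the same 2 Hz zero-lag filter, agree to < 1 deg RMSE
        (the integration constant is unobservable, so means are aligned)."""
        spec = FilterSpec("lowpass", 2, 2.0, True)
        stream, theta = generate_pendulum(noise_sd_dps=0.0)
        est = integrate(butterworth(stream.axis("sagittal"), stream.fs, spec), stream.fs)
        ref = butterworth(theta, stream.fs, spec)
        est = est - est.mean() + ref.mean()
        assert np.sqrt(np.mean((est - ref) ** 2)) < 1.0

    def test_zero_initial_angle_is_silent(self):
        stream, theta = generate_pendulum(initial_deg=0.0, duration_s=5.0)
        assert np.all(stream.axis("sagittal") == 0.0)
        assert np.all(theta == 0.0)

    def test_period_scales_with_sqrt_length(self):
        def period(L):
            s, _ = generate_pendulum(arm_length_m=L, initial_deg=5.0,
                                     duration_s=20.0, damping=0.0)
            w = s.axis("sagittal")
            crossings = np.where(np.diff(np.sign(w)) != 0)[0]
            return 2.0 * np.mean(np.diff(s.t[crossings]))

        assert period(0.92) / period(0.46) == pytest.approx(np.sqrt(2), rel=0.01)


def test_stride_geometry_homogeneity():
    """Doubling both segment lengths at fixed rotations doubles the stride."""
    base = stride_from_rotations(40.0, 35.0, 40.0, 35.0, 0.43, 0.43)
    doubled = stride_from_rotations(40.0, 35.0, 40.0, 35.0, 0.86, 0.86)
    assert doubled == pytest.approx(2 * base, rel=1e-12)
    assert stride_from_rotations(0.0, 0.0, 0.0, 0.0, 0.43, 0.43) == 0.0
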