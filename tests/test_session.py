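"""End-to-end session loop, scripted trajectories and the latency channel."""

import dataclasses

import numpy as np
import pytest

from palpsim.control import ControlConfig
from palpsim.phantom import DEFAULT_MATERIALS, Inclusion, Phantom, generate_phantom
from palpsim.session import (
    FORCE_LIMIT_N,
    LatencyModel,
    SessionConfig,
    apply_latency,
    make_trajectory,
    run_session,
)
from palpsim.subject import SubjectModel


@pytest.fixture(scope="module")
def short_cfg():
    return SessionConfig(duration=30.0, seed=9)


@pytest.fixture(scope="module")
def subject():
    return SubjectModel()


class TestMakeTrajectory:
    def test_raster_passes_near_every_inclusion(self, control_cfg):
        traj = make_trajectory("raster", {"line_spacing": 10.0, "speed": 10.0},
                               control_cfg)
        ph = generate_phantom(seed=5)
        path = traj.stage_ref
        for inc in ph.inclusions:
            d = np.hypot(path[:, 0] - inc.center_xy[0],
                         path[:, 1] - inc.center_xy[1]).min()
            assert d <= 5.0 + 1e-6

    def test_empty_waypoints_rest_at_center(self, control_cfg):
        traj = make_trajectory("waypoints", {"points": []}, control_cfg)
        assert np.all(traj.positions == 0.0)

    def test_pattern_outside_workspace_rejected(self, control_cfg):
        with pytest.raises(ValueError, match="workspace"):
            make_trajectory("waypoints",
                            {"points": [(10.0, 10.0), (150.0, 10.0)], "speed": 10.0},
                            control_cfg)

    def test_overspeed_pattern_rejected(self, control_cfg):
        with pytest.raises(ValueError, match="max_speed"):
            make_trajectory("waypoints",
                            {"points": [(10.0, 10.0), (90.0, 10.0)], "speed": 50.0},
                            control_cfg)

    def test_replay_reproduces_stage_path(self, control_cfg, short_cfg, subject,
                                          rs_params, calibration):
        ph = generate_phantom(seed=5)
        traj = make_trajectory("raster", {"line_spacing": 20.0, "speed": 10.0},
                               control_cfg)
        log = run_session(ph, subject, control_cfg, rs_params, calibration,
                          short_cfg, traj)
        recorded = log.stage[["x_mm", "y_mm"]].to_numpy()
        traj2 = make_trajectory("replay", {"path_xy": recorded}, control_cfg)
        log2 = run_session(ph, subject, control_cfg, rs_params, calibration,
                          short_cfg, traj2)
        replayed = log2.stage[["x_mm", "y_mm"]].to_numpy()
        # replayed path tracks the recording within one control step of travel
        err = np.hypot(*(replayed - recorded).T).max()
        assert err <= 10.0 * (1.0 / short_cfg.control_rate) + 1e-6


class TestApplyLatency:
    def test_zero_bound_identity(self):
        t = np.linspace(0, 1, 1001)
        v = np.sin(2 * np.pi * 3 * t)
        out = apply_latency(t, v, LatencyModel("fixed", 0.0))
        assert np.array_equal(out, v)

    def test_fixed_delay_cross_correlation_peak(self):
        t = np.arange(0, 5, 0.001)
        rng = np.random.default_rng(0)
        v = rng.normal(size=len(t))
        out = apply_latency(t, v, LatencyModel("fixed", 0.015))
        lags = np.arange(0, 40)
        corr = [np.corrcoef(v[:-lag or None], out[lag:])[0, 1] for lag in lags]
        assert lags[int(np.argmax(corr))] == 15  # 15 ms at 1 kHz sampling

    def test_jittered_delays_respect_bound(self):
        t = np.arange(0, 100, 0.001)  # 1e5 samples
        v = np.arange(len(t), dtype=float)  # strictly increasing ramp
        out = apply_latency(t, v, LatencyModel("jittered", 0.015), seed=1)
        # a ramp delayed by d(t) drops by d/dt samples: bound check
        lag = v - out
        assert np.all(lag >= -1e-9)
        assert np.all(lag <= 15.0 + 1e-6)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            LatencyModel("gamma", 0.01)


class TestRunSession:
    def test_uniform_phantom_steady_force_and_no_detections(
        self, control_cfg, subject, rs_params, calibration, short_cfg
    ):
        ph = Phantom()  # no inclusions
        traj = make_trajectory("raster", {"line_spacing": 20.0, "speed": 10.0},
                               control_cfg)
        log = run_session(ph, subject, control_cfg, rs_params, calibration,
                          short_cfg, traj)
        f = log.stage["force_N"].to_numpy()
        # after the servo settles the force holds the setpoint
        settled = f[int(5 * short_cfg.control_rate):]
        assert np.allclose(settled, short_cfg.force_setpoint, atol=1e-3)
        assert log.responses == []

    def test_force_clamp_never_exceeded(self, control_cfg, subject, rs_params,
                                        calibration, short_cfg):
        ph = generate_phantom(seed=11)
        traj = make_trajectory("raster", {"line_spacing": 10.0, "speed": 10.0},
                               control_cfg)
        log = run_session(ph, subject, control_cfg, rs_params, calibration,
                          short_cfg, traj)
        assert log.stage["force_N"].max() <= FORCE_LIMIT_N + 1e-12

    def test_rate_rises_over_stiff_inclusion(self, control_cfg, subject,
                                             rs_params, calibration):
        # single pass over one SC inclusion in the soft matrix
        ph = Phantom(inclusions=[Inclusion((50.0, 50.0), DEFAULT_MATERIALS["SC"])])
        traj = make_trajectory(
            "waypoints",
            {"points": [(20.0, 50.0), (80.0, 50.0)], "speed": 10.0},
            control_cfg,
        )
        cfg = SessionConfig(duration=12.0, seed=1)
        log = run_session(ph, subject, control_cfg, rs_params, calibration, cfg, traj)
        t = log.spikes.times
        stage = log.stage
        over = stage[(stage.x_mm - 50.0).abs() <= 5.0]["t_s"]
        t_in, t_out = over.iloc[0], over.iloc[-1]
        # compare rate while over the inclusion vs a matched pre-contact window
        width = t_out - t_in
        rate_over = np.count_nonzero((t >= t_in) & (t < t_out)) / width
        rate_before = np.count_nonzero((t >= t_in - width) & (t < t_in)) / width
        assert rate_over > rate_before

    def test_seed_reproducibility_of_logs(self, control_cfg, subject, rs_params,
                                          calibration, short_cfg):
        ph = generate_phantom(seed=11)
        traj = make_trajectory("raster", {"line_spacing": 10.0, "speed": 10.0},
                               control_cfg)
        a = run_session(ph, subject, control_cfg, rs_params, calibration,
                        short_cfg, traj)
        b = run_session(ph, subject, control_cfg, rs_params, calibration,
                        short_cfg, traj)
        assert a.serialize() == b.serialize()

    def test_zero_latency_ils_nils_identical(self, control_cfg, subject,
                                             rs_params, calibration):
        ph = generate_phantom(seed=11)
        traj = make_trajectory("raster", {"line_spacing": 20.0, "speed": 10.0},
                               control_cfg)
        logs = {}
        for mode, kind in [("ILS", "fixed"), ("NILS", "jittered")]:
            cfg = SessionConfig(duration=20.0, seed=3, mode=mode,
                                latency=LatencyModel(kind, 0.0))
            log = run_session(ph, subject, control_cfg, rs_params, calibration,
                              cfg, traj)
            s = log.serialize()
            del s["config.json"]  # configs differ by mode label only
            logs[mode] = s
        assert logs["ILS"] == logs["NILS"]

    def test_config_inconsistencies_rejected_before_run(
        self, control_cfg, subject, rs_params, calibration
    ):
        ph = generate_phantom(seed=11)
        traj = make_trajectory("raster", {}, control_cfg)
        bad_rate = SessionConfig(duration=10.0, encoder_rate=4000.0)
        with pytest.raises(ValueError, match="encoder_rate"):
            run_session(ph, subject, control_cfg, rs_params, calibration,
                        bad_rate, traj)
        small_ph = generate_phantom(size_xyz=(60.0, 60.0, 15.0), replicas=1, seed=0)
        with pytest.raises(ValueError, match="workspace"):
            run_session(small_ph, subject, control_cfg, rs_params, calibration,
                        SessionConfig(duration=10.0), traj)
        with pytest.raises(ValueError):
            SessionConfig(force_setpoint=0.6)

    def test_log_directory_roundtrip(self, control_cfg, subject, rs_params,
                                     calibration, short_cfg, tmp_path):
        ph = generate_phantom(seed=11)
        traj = make_trajectory("raster", {"line_spacing": 20.0, "speed": 10.0},
                               control_cfg)
        log = run_session(ph, subject, control_cfg, rs_params, calibration,
                          short_cfg, traj)
        log.to_dir(tmp_path / "log")
        for name in ("config.json", "hand.csv", "stage.csv", "spikes.txt",
                     "responses.csv"):
            assert (tmp_path / "log" / name).exists()
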