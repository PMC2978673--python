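import math

import numpy as np
import pytest

from pathint.core import DEFAULT_SD, NoiseSpec, StepInput, make_rng, wrap_angle
from pathint.models import (
    ACState,
    APState,
    ECState,
    EPState,
    RingState,
    RotationSensor,
    ac_step,
    ap_step,
    decode_hv,
    ec_step,
    ep_step,
    make_state,
    ring_decode_matrix,
    ring_step,
    run_pi,
    sense_heading,
    sense_rotation,
    update_ac,
    update_ap,
    update_ec,
    update_ep,
    update_ring,
)
from pathint.walks import straight_walk, turning_walk

ROT_SPEC = NoiseSpec(input_mode="direct_rotation")


class TestSenseHeading:
    def test_noise_free(self):
        assert sense_heading(0.5, NoiseSpec(), make_rng(0, "s")) == 0.5

    def test_wrong_mode(self):
        with pytest.raises(ValueError):
            sense_heading(0.0, ROT_SPEC, make_rng(0, "s"))

    def test_sample_sd(self):
        spec = NoiseSpec(delta_sd=DEFAULT_SD)
        rng = make_rng(1, "s")
        draws = np.array([sense_heading(0.0, spec, rng) for _ in range(10_000)])
        assert draws.std(ddof=1) == pytest.approx(DEFAULT_SD, rel=0.05)

    def test_wraps_near_pi(self):
        spec = NoiseSpec(delta_sd=0.1)
        rng = make_rng(2, "s")
        for _ in range(100):
            out = sense_heading(math.pi, spec, rng)
            assert -math.pi < out <= math.pi


class TestSenseRotation:
    def test_noise_free(self):
        assert sense_rotation(0.3, 0.0, ROT_SPEC, make_rng(0, "r")) == pytest.approx(0.3)

    def test_direct_sample_sd(self):
        spec = NoiseSpec(delta_sd=DEFAULT_SD, input_mode="direct_rotation")
        rng = make_rng(1, "r")
        sensor = RotationSensor(spec, rng)
        draws = np.array([sensor.measure(0.0) for _ in range(10_000)])
        assert draws.std(ddof=1) == pytest.approx(DEFAULT_SD, rel=0.05)

    def test_compass_differenced_telescopes(self):
        # on a straight walk the cumulative measured rotation error is
        # exactly (last compass error - first compass error)
        n = 200
        sd = DEFAULT_SD
        spec = NoiseSpec(delta_sd=sd, input_mode="compass_differenced")
        sensor = RotationSensor(spec, make_rng(3, "r"))
        measured = [sensor.measure(0.0, new_true_heading=0.0) for _ in range(n)]
        # replay the identical noise draws
        deltas = make_rng(3, "r").normal(0.0, sd, size=n + 1)
        assert np.allclose(measured, np.diff(deltas), atol=1e-12)
        assert sum(measured) == pytest.approx(deltas[-1] - deltas[0], abs=1e-9)

    def test_compass_differenced_needs_heading(self):
        spec = NoiseSpec(delta_sd=0.1, input_mode="compass_differenced")
        sensor = RotationSensor(spec, make_rng(0, "r"))
        with pytest.raises(ValueError):
            sensor.measure(0.0)

    def test_sensor_rejects_compass_mode(self):
        with pytest.raises(ValueError):
            RotationSensor(NoiseSpec(), make_rng(0, "r"))


class TestKernels:
    def test_ac_examples(self):
        assert ac_step(0.0, 0.0, 1.0, 0.0) == pytest.approx((1.0, 0.0))
        u, v = ac_step(0.0, 0.0, 2.0, math.pi / 2)
        assert (u, v) == pytest.approx((0.0, 2.0), abs=1e-12)
        u = v = 0.0
        for _ in range(3):
            u, v = ac_step(u, v, 1.0, 0.0)
        assert (u, v) == pytest.approx((3.0, 0.0))

    def test_ap_first_step(self):
        r, phi, nc = ap_step(0.0, 0.0, 1.0, 0.0)
        assert (r, phi, nc) == pytest.approx((1.0, 0.0, 0))

    def test_ap_matches_ac_noise_free(self):
        rng = make_rng(0, "k")
        headings = rng.uniform(-math.pi, math.pi, size=30)
        u = v = 0.0
        r = phi = 0.0
        for h in headings:
            u, v = ac_step(u, v, 1.0, h)
            r, phi, _ = ap_step(r, phi, 1.0, h)
        assert r * math.cos(phi) == pytest.approx(u, abs=1e-9)
        assert r * math.sin(phi) == pytest.approx(v, abs=1e-9)

    def test_ap_radius_clipped(self):
        r, phi, nc = ap_step(0.0, 0.0, 1.0, 0.0, eps_r=-5.0)
        assert r == 0.0 and nc == 1

    def test_ec_first_step(self):
        # step away from home: home ends up directly behind
        assert ec_step(0.0, 0.0, 1.0, 0.0) == pytest.approx((-1.0, 0.0))

    def test_ec_pure_left_turn(self):
        # 90 degree left (CCW) turn with no step: home that was behind is
        # now on the animal's left (+V')
        u, v = ec_step(-1.0, 0.0, 0.0, math.pi / 2)
        assert (u, v) == pytest.approx((0.0, 1.0), abs=1e-12)

    def test_ep_first_step(self):
        r, phi, _ = ep_step(0.0, 0.0, 1.0, 0.0)
        assert r == pytest.approx(1.0)
        assert abs(phi) == pytest.approx(math.pi)

    def test_ep_matches_ec_noise_free(self):
        rng = make_rng(1, "k")
        rots = rng.uniform(-0.5, 0.5, size=25)
        u = v = 0.0
        r, phi = 0.0, 0.0
        for rot in rots:
            u, v = ec_step(u, v, 1.0, rot)
            r, phi, _ = ep_step(r, phi, 1.0, rot)
        assert r * math.cos(phi) == pytest.approx(u, abs=1e-9)
        assert r * math.sin(phi) == pytest.approx(v, abs=1e-9)

    def test_ring_two_units_is_ac(self):
        dirs = np.array([0.0, math.pi / 2])
        moduli = np.zeros(2)
        u = v = 0.0
        rng = make_rng(2, "k")
        for h in rng.uniform(-math.pi, math.pi, size=20):
            moduli = ring_step(moduli, dirs, 1.0, h)
            u, v = ac_step(u, v, 1.0, h)
        assert moduli == pytest.approx((u, v), abs=1e-9)

    def test_ring_needs_two_units(self):
        with pytest.raises(ValueError):
            RingState.zeros(1)


class TestDecode:
    def test_ac_identity(self):
        assert decode_hv(ACState(3.0, 4.0)) == pytest.approx((3.0, 4.0))

    def test_ap_polar(self):
        x, y = decode_hv(APState(2.0, math.pi / 2))
        assert (x, y) == pytest.approx((0.0, 2.0), abs=1e-12)

    def test_ec_home_behind(self):
        assert decode_hv(ECState(-1.0, 0.0), 0.0) == pytest.approx((1.0, 0.0))

    def test_ec_frame_rotation(self):
        # facing +Y with home behind: animal is one unit along +Y from home
        x, y = decode_hv(ECState(-1.0, 0.0), math.pi / 2)
        assert (x, y) == pytest.approx((0.0, 1.0), abs=1e-12)

    def test_ep_matches_ec(self):
        ec = decode_hv(ECState(-2.0, 1.0), 0.7)
        ep = decode_hv(EPState(math.hypot(2, 1), math.atan2(1.0, -2.0)), 0.7)
        assert ep == pytest.approx(ec, abs=1e-9)

    def test_ring_decode_noise_free_straight(self):
        state = RingState.zeros(16)
        moduli = state.moduli
        for _ in range(10):
            moduli = ring_step(moduli, state.preferred_dirs, 1.0, 0.0)
        x, y = decode_hv(RingState(state.preferred_dirs, moduli))
        assert (x, y) == pytest.approx((10.0, 0.0), abs=1e-9)

    def test_ring_decode_matrix_exact_inverse(self):
        dirs = RingState.zeros(5).preferred_dirs
        dec = ring_decode_matrix(dirs)
        A = np.column_stack((np.cos(dirs), np.sin(dirs)))
        assert np.allclose(dec @ A, np.eye(2), atol=1e-12)


class TestUpdateOps:
    def test_missing_inputs_raise(self):
        spec = NoiseSpec()
        rng = make_rng(0, "u")
        inp_rot = StepInput(step_length=1.0, measured_rotation=0.0)
        inp_head = StepInput(step_length=1.0, measured_heading=0.0)
        with pytest.raises(ValueError):
            update_ac(ACState(), inp_rot, spec, rng)
        with pytest.raises(ValueError):
            update_ap(APState(), inp_rot, spec, rng)
        with pytest.raises(ValueError):
            update_ec(ECState(), inp_head, spec, rng)
        with pytest.raises(ValueError):
            update_ep(EPState(), inp_head, spec, rng)
        with pytest.raises(ValueError):
            update_ring(RingState.zeros(4), inp_rot, spec, rng)

    def test_noise_free_three_steps(self):
        spec = NoiseSpec()
        rng = make_rng(0, "u")
        state = ACState()
        inp = StepInput(step_length=1.0, measured_heading=0.0)
        for _ in range(3):
            state = update_ac(state, inp, spec, rng)
        assert (state.u, state.v) == pytest.approx((3.0, 0.0))

    def test_eps_phi_rotates_whole_representation(self):
        # applying eps_phi then decoding equals decoding then rotating
        r0, phi0 = 3.0, 0.4
        eps = 0.2
        r1, phi1, _ = ap_step(r0, phi0, 1.0, 0.1, eps_phi=eps)
        r2, phi2, _ = ap_step(r0, phi0, 1.0, 0.1)
        x2, y2 = decode_hv(APState(r2, phi2))
        rot = np.array([[math.cos(eps), -math.sin(eps)], [math.sin(eps), math.cos(eps)]])
        assert np.allclose(decode_hv(APState(r1, phi1)), rot @ np.array([x2, y2]), atol=1e-12)


class TestRunPI:
    @pytest.fixture()
    def walk(self):
        return turning_walk(100, 1.0, 0.1, make_rng(11, "path-turns"))

    def test_noise_free_all_models_zero_error(self, walk):
        for model, spec in [
            ("ac", NoiseSpec()),
            ("ap", NoiseSpec()),
            ("ring", NoiseSpec()),
            ("ec", ROT_SPEC),
            ("ep", ROT_SPEC),
        ]:
            trace = run_pi(walk, model, spec, make_rng(0, model))
            assert np.max(trace.pos_error) < 1e-9, model

    def test_noise_free_class_equivalence(self, walk):
        decoded = []
        for model, spec in [
            ("ac", NoiseSpec()),
            ("ap", NoiseSpec()),
            ("ring", NoiseSpec()),
            ("ec", ROT_SPEC),
            ("ep", ROT_SPEC),
        ]:
            t = run_pi(walk, model, spec, make_rng(0, model))
            decoded.append(np.column_stack((t.x_hat, t.y_hat)))
        for other in decoded[1:]:
            assert np.max(np.abs(other - decoded[0])) < 1e-9

    def test_bit_reproducible(self, walk):
        spec = NoiseSpec(delta_sd=DEFAULT_SD, eps_angular_sd=DEFAULT_SD,
                         eps_linear_sd=DEFAULT_SD)
        a = run_pi(walk, "ac", spec, make_rng(5, "m"))
        b = run_pi(walk, "ac", spec, make_rng(5, "m"))
        assert np.array_equal(a.pos_error, b.pos_error)
        assert np.array_equal(a.states, b.states)

    def test_error_is_frame_invariant(self, walk):
        # positional error equals the ego-frame mismatch norm (isometry)
        spec = ROT_SPEC.replace(delta_sd=DEFAULT_SD)
        trace = run_pi(walk, "ec", spec, make_rng(6, "m"))
        from pathint.models import ego_frame_headings

        frames = ego_frame_headings(walk)
        for k in (10, 50, 100):
            # true home position in the body frame at step k
            c, s = math.cos(frames[k]), math.sin(frames[k])
            px, py = walk.positions[k]
            true_u = c * (-px) + s * (-py)
            true_v = -s * (-px) + c * (-py)
            su, sv = trace.states[k]
            ego_err = math.hypot(su - true_u, sv - true_v)
            assert ego_err == pytest.approx(trace.pos_error[k], abs=1e-9)

    def test_ec_diverges_ac_bounded(self):
        # matched input-noise scale: EC (IDW-like) ends far worse than AC
        spec_ac = NoiseSpec(delta_sd=DEFAULT_SD)
        spec_ec = ROT_SPEC.replace(delta_sd=DEFAULT_SD)
        walk = straight_walk(400, 1.0)
        err_ac = [
            run_pi(walk, "ac", spec_ac, make_rng(i, "ac")).pos_error[-1]
            for i in range(30)
        ]
        err_ec = [
            run_pi(walk, "ec", spec_ec, make_rng(i, "ec")).pos_error[-1]
            for i in range(30)
        ]
        assert np.mean(err_ec) > 5 * np.mean(err_ac)

    def test_input_mode_validation(self, walk):
        with pytest.raises(ValueError):
            run_pi(walk, "ap", ROT_SPEC, make_rng(0, "m"))
        with pytest.raises(ValueError):
            run_pi(walk, "ec", NoiseSpec(), make_rng(0, "m"))
        with pytest.raises(ValueError):
            run_pi(walk, "xc", NoiseSpec(), make_rng(0, "m"))

    def test_ac_idiothetic_input(self, walk):
        # rotation-integrating AC tracks exactly when noise free
        trace = run_pi(walk, "ac", ROT_SPEC, make_rng(0, "m"))
        assert np.max(trace.pos_error) < 1e-9
        trace_cd = run_pi(
            walk, "ac", NoiseSpec(input_mode="compass_differenced"), make_rng(0, "m")
        )
        assert np.max(trace_cd.pos_error) < 1e-9

    def test_trace_csv(self, walk, tmp_path):
        trace = run_pi(walk, "ap", NoiseSpec(delta_sd=0.1), make_rng(0, "m"))
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "step,r,phi,x_hat,y_hat,pos_error"
        assert len(out.read_text().splitlines()) == walk.n_steps + 2

    def test_clipping_counted(self):
        walk = straight_walk(200, 0.01)
        spec = NoiseSpec(eps_linear_sd=1.0)
        trace = run_pi(walk, "ap", spec, make_rng(4, "clip"))
        assert trace.n_clipped > 0

    def test_make_state(self):
        assert isinstance(make_state("ep"), EPState)
        with pytest.raises(ValueError):
            make_state("nope")
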