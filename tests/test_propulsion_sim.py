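"""Propulsion model: step-out averaging, bistable state selection, kinematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucoswim import (
    CoatingParams,
    FluidField,
    ParticleState,
    make_mucus_field,
    mean_rotation_rate,
    propulsion_sign,
    propulsion_speed,
    sample_mobility,
    simulate_fixed_heading,
    step,
)
from mucoswim.propulsion_sim import MobilityBoundsError

from .oracles import rotor_average_rate


class TestMeanRotationRate:
    @pytest.mark.parametrize(
        "f,f_c,expected",
        [
            (10.0, 20.0, 10.0),  # synchronous below step-out
            (5.0, 0.0, 0.0),  # no coupling, no net rotation
            (5.0, 4.0, 2.0),  # asynchronous: 5 - sqrt(25 - 16)
        ],
    )
    def test_reference_values(self, f, f_c, expected):
        assert mean_rotation_rate(f, f_c) == pytest.approx(expected, abs=1e-12)

    def test_matches_rotor_ode_oracle_at_spot_check(self):
        """The closed form equals the integrated rotor average (5, 4) -> 2 Hz."""
        oracle = rotor_average_rate(5.0, 4.0)
        assert mean_rotation_rate(5.0, 4.0) == pytest.approx(oracle, rel=1e-4)

    def test_continuous_at_stepout_and_nonincreasing_above(self):
        f_c = 10.0
        below = mean_rotation_rate(f_c - 1e-9, f_c)
        at = mean_rotation_rate(f_c, f_c)
        just_above = mean_rotation_rate(f_c + 1e-9, f_c)
        assert at == pytest.approx(below, abs=1e-6)
        assert just_above == pytest.approx(at, abs=1e-3)
        # monotone decreasing above step-out (asymptotically ~ f_c^2 / 2f)
        fs = np.geomspace(f_c * 1.001, f_c * 20, 80)
        rates = mean_rotation_rate(fs, f_c)
        assert np.all(np.diff(rates) < 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mean_rotation_rate(-1.0, 5.0)


class TestPropulsionSign:
    def test_deterministic_above_threshold(self, rng):
        assert propulsion_sign(1.0, 0.1, rng) == 1
        assert propulsion_sign(-1.0, 0.1, rng) == -1

    def test_unbiased_below_threshold(self):
        rng = np.random.default_rng(7)
        draws = [propulsion_sign(0.0, 0.1, rng) for _ in range(10_000)]
        frac_plus = np.mean(np.array(draws) == 1)
        assert 0.485 <= frac_plus <= 0.515


class TestPropulsionSpeed:
    def test_linear_regime_is_c_times_f(self, plain_coating):
        for f in (1.0, 7.0, 19.0):
            v = propulsion_speed(plain_coating, f, beta=0.5, B_s=0.0, m_local=1.0)
            assert v == pytest.approx(plain_coating.c * f, abs=1e-12)

    def test_null_coating_gives_zero(self):
        coating = CoatingParams(name="null", c=0.0, f_c0=60.0)
        assert propulsion_speed(coating, 50.0, 0.5, 1.0, 2.0) == 0.0

    def test_asynchronous_closed_form(self):
        coating = CoatingParams(name="x", c=0.3, f_c0=50.0, p=0.0)
        v = propulsion_speed(coating, 100.0, 0.5, 0.0, 1.0)
        expected = 0.3 * (100.0 - math.sqrt(100.0**2 - 50.0**2))
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(0.3 * 13.397, rel=1e-3)

    def test_noise_requires_rng_and_keeps_speed_positive(self):
        noisy = CoatingParams(name="n", c=0.3, f_c0=60.0, sigma_U=0.5)
        with pytest.raises(ValueError):
            propulsion_speed(noisy, 10.0, 0.5, 0.0, 1.0)
        rng = np.random.default_rng(0)
        speeds = propulsion_speed(noisy, 10.0, 0.5, 0.0, np.ones(5000), rng)
        assert np.all(speeds >= 0)

    def test_speed_linear_in_c(self, plain_coating):
        doubled = CoatingParams(name="d", c=2 * plain_coating.c, f_c0=60.0)
        v1 = propulsion_speed(plain_coating, 12.0, 0.5, 0.0, 1.3)
        v2 = propulsion_speed(doubled, 12.0, 0.5, 0.0, 1.3)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)


class TestStep:
    def test_displacement_follows_heading_convention(self):
        state = ParticleState(x=0.0, y=0.0, s=1)
        out = step(state, theta=0.0, speed=10.0, dt=0.1)
        assert (out.x, out.y) == pytest.approx((-1.0, 0.0), abs=1e-12)

    def test_sign_flip_mirrors_displacement(self):
        plus = step(ParticleState(s=1), theta=0.7, speed=5.0, dt=0.2)
        minus = step(ParticleState(s=-1), theta=0.7, speed=5.0, dt=0.2)
        assert (minus.x, minus.y) == pytest.approx((-plus.x, -plus.y), abs=1e-12)

    def test_path_length_equals_speed_times_duration(self):
        state = ParticleState()
        dt = 1.0 / 30.0
        for _ in range(300):
            state = step(state, theta=1.2, speed=12.0, dt=dt)
        path = math.hypot(state.x, state.y)
        assert path == pytest.approx(12.0 * 300 * dt, abs=1e-9)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            ParticleState(s=0)


class TestMobilityField:
    def test_homogeneous_field_is_unity(self, homogeneous_fluid):
        assert sample_mobility(homogeneous_fluid, 12.3, -45.6) == 1.0

    def test_grid_node_identity(self):
        fluid = make_mucus_field(
            extent=(0.0, 100.0, 0.0, 100.0), grid_step=10.0, cv=0.3, seed=3
        )
        ix, iy = 4, 7
        assert fluid.sample(fluid.x[ix], fluid.y[iy]) == pytest.approx(
            fluid.m[iy, ix], rel=1e-12
        )

    def test_mean_near_unity_under_random_queries(self):
        fluid = make_mucus_field(cv=0.3, seed=11)
        rng = np.random.default_rng(5)
        xs = rng.uniform(-190, 190, 10_000)
        ys = rng.uniform(-190, 190, 10_000)
        vals = fluid.sample(xs, ys)
        assert np.all(vals > 0)
        assert abs(vals.mean() - 1.0) < 3 * vals.std() / math.sqrt(len(vals)) + 0.02

    def test_out_of_extent_query_raises(self, homogeneous_fluid):
        with pytest.raises(MobilityBoundsError):
            homogeneous_fluid.sample(1e4, 0.0)

    def test_save_load_round_trip(self, tmp_path):
        fluid = make_mucus_field(cv=0.2, seed=9)
        fluid.save(tmp_path / "field")
        loaded = FluidField.load(tmp_path / "field")
        assert np.allclose(loaded.m, fluid.m)
        assert loaded.cv == fluid.cv
        assert loaded.sample(5.0, 5.0) == pytest.approx(fluid.sample(5.0, 5.0))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    f=st.floats(0.1, 50.0),
    f_c=st.floats(0.0, 50.0),
)
def test_mean_rotation_rate_bounded_by_drive(f, f_c):
    rate = mean_rotation_rate(f, f_c)
    assert 0.0 <= rate <= f + 1e-12


class TestFixedHeadingEnsemble:
    def test_linear_law_recovered_exactly(self, plain_coating, homogeneous_fluid):
        """Noise off, below step-out: x-velocity at theta=pi is exactly c*f."""
        sim = simulate_fixed_heading(
            plain_coating,
            f=10.0,
            beta=0.5,
            B_s=0.0,
            fluid=homogeneous_fluid,
            duration=5.0,
            dt=1.0 / 30.0,
            theta=math.pi,
            start_xy=np.zeros((3, 2)),
            signs=np.ones(3),
            rng=np.random.default_rng(0),
        )
        assert np.allclose(sim["mean_vx"], plain_coating.c * 10.0, atol=1e-9)
        assert np.allclose(sim["mean_vy"], 0.0, atol=1e-12)

    def test_zero_field_ensemble_mean_displacement_vanishes(self, plain_coating):
        """At B_s = 0 random state selection makes mean signed drift ~ 0."""
        rng = np.random.default_rng(21)
        n = 400
        signs = np.array([propulsion_sign(0.0, 0.1, rng) for _ in range(n)])
        sim = simulate_fixed_heading(
            plain_coating,
            f=10.0,
            beta=0.5,
            B_s=0.0,
            fluid=None,
            duration=2.0,
            dt=1.0 / 30.0,
            theta=math.pi,
            start_xy=np.zeros((n, 2)),
            signs=signs,
            rng=rng,
        )
        vx = sim["mean_vx"]
        assert abs(vx.mean()) < 3 * vx.std(ddof=1) / math.sqrt(n)
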