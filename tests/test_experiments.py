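"""End-to-end experiment protocols and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mucoswim import (
    SWEEP_PROTOCOLS,
    CoatingParams,
    NavigationTimeout,
    SweepProtocol,
    run_beta_sweep,
    run_frequency_sweep,
    run_static_sweep,
    run_trajectory,
)
from mucoswim.experiments import main
from mucoswim.synthetic_data import make_mucus_field
from mucoswim.tracking_velocity import fit_through_origin


@pytest.fixture(scope="module")
def homog():
    return make_mucus_field(
        extent=(-300.0, 300.0, -300.0, 300.0), grid_step=20.0, cv=0.0, seed=0
    )


class TestProtocols:
    def test_published_presets_validate(self):
        assert set(SWEEP_PROTOCOLS) == {"sweep_1_19", "sweep_5_50", "sweep_10_100"}
        p = SWEEP_PROTOCOLS["sweep_1_19"]
        assert len(p.frequencies()) == 19
        assert p.n_particles == {
            "avidin": 9,
            "biotin": 9,
            "biotin_peg3_amine": 10,
            "biotin_chitosan": 7,
        }
        assert len(SWEEP_PROTOCOLS["sweep_5_50"].frequencies()) == 10
        assert len(SWEEP_PROTOCOLS["sweep_10_100"].frequencies()) == 10

    def test_amplitude_cap_rejects_out_of_envelope_protocol(self):
        rogue = SweepProtocol(
            name="rogue", f_min=10, f_max=100, f_step=10, beta=0.5,
            n_particles={"avidin": 1},
        )
        with pytest.raises(ValueError, match="cap"):
            run_frequency_sweep(rogue)


class TestFrequencySweep:
    def test_noise_free_linear_regime_recovers_slope(self, homog):
        coating = CoatingParams(name="k", c=0.27, f_c0=60.0, sigma_U=0.0)
        bundle = run_frequency_sweep(
            "sweep_1_19", coatings={"k": coating}, fluid=homog, seed=0,
            duration=2.0,
        )
        fit = bundle.fits["k"]
        assert fit.slope == pytest.approx(0.27, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproducible(self):
        a = run_frequency_sweep("sweep_1_19", seed=7, duration=1.0)
        b = run_frequency_sweep("sweep_1_19", seed=7, duration=1.0)
        pd.testing.assert_frame_equal(a.tables["trials"], b.tables["trials"])
        assert a.fits["avidin"] == b.fits["avidin"]

    def test_step_out_shrinks_linear_region(self):
        """10-100 Hz regime: the 10-50 Hz sub-fit is more linear than the full fit."""
        bundle = run_frequency_sweep("sweep_10_100", seed=3, duration=5.0)
        for name in ("avidin", "biotin_chitosan"):
            prof = bundle.tables[f"profile_{name}"]
            sub = prof[prof["f_Hz"] <= 50.0]
            r2_sub = fit_through_origin(sub).r2
            r2_full = fit_through_origin(prof).r2
            assert r2_sub > r2_full

    def test_bundle_save(self, tmp_path):
        bundle = run_frequency_sweep("sweep_1_19", seed=1, duration=1.0)
        out = bundle.save(tmp_path / "run")
        assert (out / "metadata.json").exists()
        assert (out / "trials.csv").exists()
        fits = json.loads((out / "fits.json").read_text())
        assert set(fits) == set(bundle.fits)


class TestBetaSweep:
    def test_flat_when_no_beta_coupling(self, homog):
        """A coating with beta-independent f_c stays synchronous and flat."""
        coating = CoatingParams(name="flat", c=0.3, f_c0=50.0, p=0.0, sigma_U=0.0)
        bundle = run_beta_sweep(
            coatings={"flat": coating}, fluid=homog, seed=0, duration=2.0
        )
        v = bundle.tables["beta_sweep_flat"]["mean_um_s"]
        assert np.allclose(v, v.iloc[0], rtol=1e-9)

    def test_single_beta_single_row(self, homog):
        coating = CoatingParams(name="one", c=0.3, f_c0=50.0, sigma_U=0.0)
        bundle = run_beta_sweep(
            coatings={"one": coating}, inv_beta_values=[2.0], fluid=homog,
            seed=0, duration=1.0,
        )
        assert len(bundle.tables["beta_sweep_one"]) == 1

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            run_beta_sweep(inv_beta_values=[0.0])


class TestStaticSweep:
    def test_sign_deterministic_above_threshold_and_odd_structure(self):
        bundle = run_static_sweep(seed=11, duration=3.0)
        tab = bundle.tables["static_sweep_avidin"]
        B = tab["B_s_mT"].to_numpy()
        v = tab["mean_vx_um_s"].to_numpy()
        above = np.abs(B) > 0.1
        assert np.all(np.sign(v[above]) == np.sign(B[above]))
        # exactly one sign change across the ordered sweep
        signs = np.sign(v)
        assert int((np.diff(signs) != 0).sum()) == 1

    def test_both_states_seen_at_zero_field(self):
        rows = []
        for seed in range(40):
            bundle = run_static_sweep(
                seed=seed, B_s_values=np.array([0.0]), n_trials=1,
                n_particles={"avidin": 1}, duration=0.5,
            )
            rows.append(bundle.tables["static_sweep_avidin"]["frac_plus"].iloc[0])
        fracs = np.array(rows)
        assert (fracs == 1.0).any() and (fracs == 0.0).any()


class TestTrajectory:
    def test_letter_completed_with_consistent_velocity(self, homog):
        coating = CoatingParams(name="c", c=0.3, f_c0=40.0, sigma_U=0.0)
        bundles = [
            run_trajectory(label, coating=coating, fluid=homog, seed=2)
            for label in ("A", "U")
        ]
        means = []
        for b in bundles:
            assert b.metadata["status"] == "ok"
            means.append(b.tables["velocity"]["speed_um_s"].mean())
        assert abs(means[0] - means[1]) / means[0] < 0.05

    def test_heterogeneous_mucus_separates_particles(self):
        """Particles in thick vs thin mucus pockets move at very different speeds."""
        fluid = make_mucus_field(cv=0.4, correlation_length=40.0, seed=9)
        coating = CoatingParams(name="c", c=0.3, f_c0=40.0, sigma_U=0.0)
        iy_hi, ix_hi = np.unravel_index(np.argmax(fluid.m), fluid.m.shape)
        iy_lo, ix_lo = np.unravel_index(np.argmin(fluid.m), fluid.m.shape)
        from mucoswim.propulsion_sim import simulate_fixed_heading

        speeds = []
        for iy, ix in ((iy_hi, ix_hi), (iy_lo, ix_lo)):
            start = np.array([[np.clip(fluid.x[ix], -150, 150),
                               np.clip(fluid.y[iy], -150, 150)]])
            sim = simulate_fixed_heading(
                coating, f=15.0, beta=0.5, B_s=0.0, fluid=fluid, duration=3.0,
                dt=1 / 30, theta=np.pi, start_xy=start, signs=np.ones(1),
                rng=np.random.default_rng(0),
            )
            speeds.append(abs(sim["mean_vx"][0]))
        hi, lo = max(speeds), min(speeds)
        assert (hi - lo) / hi > 0.20

    def test_timeout_propagated_with_partial_bundle(self, homog):
        dead = CoatingParams(name="dead", c=0.0, f_c0=40.0)
        with pytest.raises(NavigationTimeout) as exc_info:
            run_trajectory("A", coating=dead, fluid=homog, seed=0, timeout=2.0)
        assert exc_info.value.bundle.metadata["status"] == "timeout"


class TestCli:
    def test_static_sweep_subcommand(self, tmp_path):
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({"duration": 0.5, "n_trials": 1}))
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["static-sweep", "--config", str(cfg), "--seed", "1",
             "--out", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "metadata.json").exists()

    def test_render_fixtures_subcommand(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["render-fixtures", "--n-frames", "3", "--seed", "2",
             "--out", str(tmp_path / "fx")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "fx" / "stack.tif").exists()
        assert (tmp_path / "fx" / "stack.json").exists()
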