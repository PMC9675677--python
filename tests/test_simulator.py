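import numpy as np
import pytest

from cicrsim import (GridSpec, ModelParams, improved_params, run_basic,
                     run_improved, run_scenario, total_mass)
from cicrsim.fixtures import gaussian_profile, tiny_grid
from cicrsim.simulator import default_sensor_positions, initial_state


class TestReproducibility:
    def test_identical_seed_gives_identical_traces(self, grid1d, params):
        a = run_basic(params, grid1d, seed=7, sensors=[0.0, 5.0])
        b = run_basic(params, grid1d, seed=7, sensors=[0.0, 5.0])
        for var in a.traces.data:
            assert np.array_equal(a.traces.data[var], b.traces.data[var])

    def test_different_seed_diverges_with_high_firing(self, grid1d):
        p = ModelParams(P_max=5e4)
        a = run_basic(p, grid1d, seed=1, sensors=[0.0, 5.0])
        b = run_basic(p, grid1d, seed=2, sensors=[0.0, 5.0])
        assert not np.array_equal(a.traces.data["C"], b.traces.data["C"])


class TestCouplingConservation:
    def test_basic_model_conserves_total_calcium(self):
        """With the exterior leak and dye/buffer off, +-J_CRU, +-J_SRleak and
        -+J_pump cancel pairwise, so the summed cytosol+SR content is
        invariant."""
        params = ModelParams(k=0.0)
        grid = tiny_grid(ndim=1, duration=20.0)
        r = run_basic(params, grid, seed=0, include_buffer_dye=False,
                      sensors=[0.0, 5.0], snapshot_times=[0.0, 20.0])
        def mass(t):
            return (total_mass(r.snapshots["C"][t], grid.dx)
                    + total_mass(r.snapshots["C_S"][t], grid.dx))
        assert mass(20.0) == pytest.approx(mass(0.0), rel=1e-6)


class TestQuiescentRelaxation:
    def test_no_firing_without_initiation(self):
        params = ModelParams(P_max=0.0)
        grid = tiny_grid(ndim=1, duration=10.0)
        r = run_basic(params, grid, seed=0, force_init=False,
                      sensors=[0.0, 5.0])
        C = r.traces.data["C"]
        CS = r.traces.data["C_S"]
        # SR bleeds monotonically into the cytosol toward the leak balance
        assert np.all(np.diff(CS, axis=0) <= 1e-12)
        assert np.all(np.diff(C, axis=0) >= -1e-12)
        # and stays far from spark amplitudes
        assert C.max() < 1.0


class TestDimensionalConsistency:
    def test_2d_collapses_to_1d_for_y_uniform_forcing(self):
        params = ModelParams(P_max=0.0)
        g1 = tiny_grid(ndim=1, duration=5.0)
        g2 = tiny_grid(ndim=2, duration=5.0)
        bump1 = 0.1 + gaussian_profile(g1, amplitude=5.0, width_um=1.0)
        st1 = initial_state(params, g1, "basic")
        st1.C = bump1
        st2 = initial_state(params, g2, "basic")
        st2.C = np.tile(bump1[:, None], (1, g2.ny))
        kw = dict(seed=0, force_init=False, sensors=[1.2, 4.8],
                  sensor_mode="literal")
        r1 = run_basic(params, g1, init=st1, **kw)
        r2 = run_basic(params, g2, init=st2, **kw)
        for var in ("C", "C_S", "CaF"):
            a, b = r1.traces.data[var], r2.traces.data[var]
            assert np.max(np.abs(a - b)) < 1e-5 * max(1.0, np.max(np.abs(a)))


class TestBufferingSuppression:
    def test_buffered_peaks_never_exceed_unbuffered(self):
        params = improved_params(firing_rule="literal")
        grid = tiny_grid(ndim=1, duration=30.0)
        sensors = [1.2, 2.8, 4.8]
        buf = run_improved(params, grid, seed=3, sensors=sensors,
                           include_buffer_dye=True)
        unbuf = run_improved(params, grid, seed=3, sensors=sensors,
                             include_buffer_dye=False)
        assert np.all(buf.summary.peak_c <= unbuf.summary.peak_c + 1e-9)


class TestSensorSemantics:
    def test_probes_move_off_release_columns(self, params):
        grid = tiny_grid(ndim=1, duration=1.0)
        r = run_basic(params, grid, seed=0, sensors=[5.0, 3.3])
        # 5.0 um is the forced-initiation column: probe shifts half a
        # channel spacing away; 3.3 um is off-lattice and stays put
        assert r.traces.sensor_x[0] == pytest.approx(4.0)
        assert r.traces.sensor_x[1] == pytest.approx(3.2)

    def test_literal_mode_keeps_requested_nodes(self, params):
        grid = tiny_grid(ndim=1, duration=1.0)
        r = run_basic(params, grid, seed=0, sensors=[4.0],
                      sensor_mode="literal")
        # 4.0 um is a channel column; literal mode records it anyway
        assert r.traces.sensor_x[0] == pytest.approx(4.0)

    def test_default_layout_spans_published_positions(self):
        g = GridSpec(ndim=1, duration=1.0)
        xs = default_sensor_positions(g)
        assert len(xs) == 7
        assert xs[-1] == pytest.approx(50.0)
        assert xs[0] == 0.0


class TestScenarios:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenario("fig9", seed=0)

    def test_scenario_metadata_and_variants(self):
        r = run_scenario("fig2-1d", seed=0, grid_overrides={"duration": 1.0})
        assert r.meta["scenario"] == "fig2-1d"
        assert r.meta["variant"] == "basic-1d"
        assert r.meta["params"]["firing_rule"] == "rate"
        r = run_scenario("fig5-unbuffered", seed=0,
                         grid_overrides={"ndim": 1, "duration": 1.0})
        assert r.meta["variant"] == "improved-1d"
        assert r.meta["include_buffer_dye"] is False
        assert r.meta["params"]["firing_rule"] == "literal"
        assert "CaF" not in r.traces.data

    def test_meta_echoes_resolved_config(self, grid1d, params):
        r = run_basic(params, grid1d, seed=5, sensors=[0.0, 5.0])
        assert r.meta["seed"] == 5
        assert r.meta["grid"]["Lx"] == grid1d.Lx
        assert r.meta["params"]["V_pump"] == params.V_pump
        assert r.traces.times[-1] <= grid1d.duration + 1e-9


class TestStrictStability:
    def test_warnings_escalate_to_errors_on_request(self, params):
        from cicrsim import ValidationError
        grid = GridSpec(Lx=10, Ly=1.6, dx=0.4, dy=0.8 / 3, ndim=1,
                        dt=0.0125, duration=0.05)
        with pytest.raises(ValidationError, match="stiffness"):
            run_basic(params, grid, 0, sensors=[1.2], strict_stability=True)
        run_basic(params, grid, 0, sensors=[1.2])  # warning-only by default


class TestImprovedVariant:
    def test_equal_concentrations_silence_ryr(self):
        # with C == C_S the RyR term vanishes, so one step with gates open
        # matches one step with no release sites at all
        params = improved_params(P_max=0.0)
        grid = tiny_grid(ndim=1, duration=0.003125)
        st = initial_state(params, grid, "improved")
        st.C_S = np.full(grid.shape, params.C_rest)
        kw = dict(seed=0, sensors=[1.2, 4.0], sensor_mode="literal",
                  cytosol_release="ryr", snapshot_times=[grid.dt],
                  sample_stride=1)
        import copy
        open_run = run_improved(params, grid, init=copy.deepcopy(st),
                                force_init=True, **kw)
        quiet_run = run_improved(params, grid, init=copy.deepcopy(st),
                                 force_init=False, **kw)
        for var in ("C", "C_S"):
            assert np.array_equal(open_run.snapshots[var][grid.dt],
                                  quiet_run.snapshots[var][grid.dt])

    def test_sr_dye_pool_tracks_blink(self):
        params = improved_params(firing_rule="literal")
        grid = tiny_grid(ndim=1, duration=30.0)
        r = run_improved(params, grid, seed=1, sensors=[4.0])
        assert "CaF_SR" in r.traces.data
        assert r.summary.blink_amplitude is not None
        assert r.summary.blink_amplitude >= 0.0
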