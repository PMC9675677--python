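import numpy as np
import pytest

from cicrsim import GridSpec, ModelParams, ValidationError
from cicrsim.fixtures import tiny_grid
from cicrsim.gating import (CLOSED, OPEN, SPENT, CRULattice, build_lattice,
                            firing_probability, force_initiation, step_gates)


class TestLattice:
    def test_default_domain_counts(self):
        g1 = GridSpec(ndim=1, duration=1.0)
        assert build_lattice(g1).n_channels == 51       # x = 0, 2, ..., 100
        g2 = GridSpec(ndim=2, duration=1.0)
        assert build_lattice(g2).n_channels == 51 * 26  # y = 0, 0.8, ..., 20

    def test_channels_start_closed_on_lattice(self):
        g = tiny_grid(ndim=2)
        lat = build_lattice(g)
        assert np.all(lat.state == CLOSED)
        assert np.all(lat.remaining_open == 0.0)
        sx = round(g.lx_chan / g.dx)
        sy = round(g.ly_chan / g.dy)
        assert np.all(lat.positions[:, 0] % sx == 0)
        assert np.all(lat.positions[:, 1] % sy == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CRULattice(np.array([[0], [5]]), np.zeros(1, dtype=np.int8),
                       np.zeros(2), ndim=1)


class TestFiringProbability:
    def test_saturates_at_pmax(self, iparams):
        P = firing_probability(np.array([1e9]), iparams)
        assert P[0] == pytest.approx(iparams.P_max, rel=1e-6)

    def test_zero_at_zero(self, iparams):
        assert firing_probability(np.array([0.0]), iparams)[0] == 0.0

    def test_half_saturation_printed_form(self, iparams):
        # denominator K + C^n as printed: half-max where C^n = K_prob
        C = iparams.K_prob ** (1.0 / iparams.n_prob)
        P = firing_probability(np.array([C]), iparams)
        assert P[0] == pytest.approx(iparams.P_max / 2.0, rel=1e-12)

    def test_hill_denominator_variant(self):
        ip = ModelParams(kprob_hill=True).internal()
        P = firing_probability(np.array([ip.K_prob]), ip)
        assert P[0] == pytest.approx(ip.P_max / 2.0, rel=1e-12)


class TestStepGates:
    def test_zero_pmax_only_counts_down(self, rng):
        ip = ModelParams(P_max=0.0).internal()
        g = tiny_grid(ndim=1)
        lat = build_lattice(g)
        lat.state[0] = OPEN
        lat.remaining_open[0] = 2 * g.dt
        C = np.full(g.shape, 100.0)
        step_gates(lat, C, ip, g.dt, rng)
        assert lat.state[0] == OPEN
        step_gates(lat, C, ip, g.dt, rng)
        assert lat.state[0] == SPENT
        assert np.all(lat.state[1:] == CLOSED)

    def test_forced_uniform_zero_fires_everything(self, iparams, rng_zero):
        g = tiny_grid(ndim=1)
        lat = build_lattice(g)
        C = np.full(g.shape, 1.0)  # P > 0 everywhere
        step_gates(lat, C, iparams, g.dt, rng_zero)
        assert np.all(lat.state == OPEN)
        assert np.all(lat.remaining_open == iparams.T_open)

    def test_spent_channels_never_reopen(self, iparams, rng_zero):
        g = tiny_grid(ndim=1)
        lat = build_lattice(g)
        C = np.full(g.shape, 1.0)
        step_gates(lat, C, iparams, g.dt, rng_zero)
        for _ in range(int(iparams.T_open / g.dt) + 1):
            step_gates(lat, C, iparams, g.dt, rng_zero)
        assert np.all(lat.state == SPENT)
        step_gates(lat, C, iparams, g.dt, rng_zero)
        assert np.all(lat.state == SPENT)

    def test_open_plus_spent_nondecreasing(self, iparams):
        g = tiny_grid(ndim=1)
        lat = build_lattice(g)
        rng = np.random.Generator(np.random.PCG64(5))
        C = np.full(g.shape, 50.0)
        prev = 0
        ip = ModelParams(P_max=5e4).internal()  # high rate so some fire
        for _ in range(200):
            step_gates(lat, C, ip, g.dt, rng)
            now = int(np.sum(lat.state != CLOSED))
            assert now >= prev
            prev = now

    def test_seed_determinism(self, iparams):
        g = tiny_grid(ndim=1)
        C = np.full(g.shape, 30.0)
        ip = ModelParams(P_max=5e4).internal()
        histories = []
        for _ in range(2):
            lat = build_lattice(g)
            rng = np.random.Generator(np.random.PCG64(42))
            hist = []
            for _ in range(100):
                step_gates(lat, C, ip, g.dt, rng)
                hist.append(lat.state.copy())
            histories.append(np.array(hist))
        assert np.array_equal(histories[0], histories[1])

    def test_probability_above_one_rejected(self):
        ip = ModelParams(P_max=1e9).internal()
        g = tiny_grid(ndim=1)
        lat = build_lattice(g)
        with pytest.raises(ValidationError, match="P\\*dt"):
            step_gates(lat, np.full(g.shape, 1e6), ip, g.dt,
                       np.random.default_rng(0))

    def test_literal_rule_threshold(self, rng_zero, rng_one):
        ip = ModelParams(firing_rule="literal").internal()
        g = tiny_grid(ndim=1)
        C = np.full(g.shape, 5.0)
        lat = build_lattice(g)
        step_gates(lat, C, ip, g.dt, rng_one)   # u ~ 1 > P/P_max
        assert np.all(lat.state == CLOSED)
        step_gates(lat, C, ip, g.dt, rng_zero)  # u = 0 < P/P_max
        assert np.all(lat.state == OPEN)

    def test_empirical_firing_frequency_matches_p_dt(self):
        """Per-step firing fraction over 1e5 Bernoulli trials is within
        3 standard errors of P(C)*dt."""
        n = 100_000
        ip = ModelParams(P_max=2e4).internal()  # 20/ms: appreciable p per step
        g = tiny_grid(ndim=1)
        C_val = 10.0
        lat = CRULattice(np.zeros((n, 1), dtype=np.intp),
                         np.zeros(n, dtype=np.int8), np.zeros(n), ndim=1)
        C = np.full(g.shape, C_val)
        p_expect = float(firing_probability(np.array([C_val]), ip)[0] * g.dt)
        rng = np.random.Generator(np.random.PCG64(2024))
        step_gates(lat, C, ip, g.dt, rng)
        frac = np.mean(lat.state == OPEN)
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(frac - p_expect) < 3 * se


class TestForceInitiation:
    def test_two_central_columns_open_2d(self, iparams):
        g = GridSpec(ndim=2, duration=1.0)
        lat = build_lattice(g)
        force_initiation(lat, g, iparams)
        open_pos = lat.open_indices()
        xs = np.unique(open_pos[:, 0]) * g.dx
        assert np.allclose(xs, [50.0, 50.4])
        assert len(open_pos) == 2 * 26  # every channel row in both columns

    def test_two_nodes_open_1d(self, iparams):
        g = GridSpec(ndim=1, duration=1.0)
        lat = build_lattice(g)
        force_initiation(lat, g, iparams)
        assert len(lat.open_indices()) == 2

    def test_idempotent(self, iparams):
        g = tiny_grid(ndim=1)
        lat = build_lattice(g)
        force_initiation(lat, g, iparams)
        snapshot = (lat.positions.copy(), lat.state.copy(), lat.remaining_open.copy())
        force_initiation(lat, g, iparams)
        assert np.array_equal(lat.positions, snapshot[0])
        assert np.array_equal(lat.state, snapshot[1])
        assert np.array_equal(lat.remaining_open, snapshot[2])

    def test_off_lattice_columns_are_appended(self, iparams):
        # on the full domain x = 50 um is a lattice column but 50.4 um is
        # not; the off-lattice column is added as an extra release site
        g = GridSpec(ndim=1, duration=1.0)
        lat = build_lattice(g)
        n0 = lat.n_channels
        force_initiation(lat, g, iparams)
        assert lat.n_channels == n0 + 1
        assert len(lat.open_indices()) == 2
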