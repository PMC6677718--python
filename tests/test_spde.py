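"""Euler–Maruyama stepper of the discretized SPDE."""

import numpy as np
import pytest

from hybridrd import (Domain, EMConfig, HybridState, Partition, ReactionSpec,
                      SpeciesSpec, build_model, em_step, spde_only_run)
from hybridrd.hybrid import build_sim
from hybridrd.core import RNGStream


def _diffusion_model(K=4, D=0.8, init=None):
    dom = Domain.from_compartments(K=K, h=1.0)
    if init is None:
        init = np.zeros((1, K), dtype=int)
        init[0, 0] = 100
    return build_model(dom, [SpeciesSpec("S", D)], [], init)


class TestEmStep:
    def test_uniform_state_unchanged_without_noise(self, rng):
        model = _diffusion_model(init=np.full((1, 4), 30))
        part = Partition.all_spde(4, alpha=5)
        hs = HybridState.from_compartment_counts(model, part)
        out = em_step(hs, model, EMConfig(dt=1e-3, noise_on=False), rng)
        assert np.allclose(out.grid, hs.grid)   # zero discrete Laplacian

    def test_mass_conserved_with_noise(self, rng):
        model = _diffusion_model()
        part = Partition.all_spde(4, alpha=5)
        hs = HybridState.from_compartment_counts(model, part)
        for _ in range(200):
            hs = em_step(hs, model, EMConfig(dt=1e-3), rng)
            assert hs.total() == pytest.approx(100.0, rel=1e-9)

    def test_negative_pair_sum_disables_noise_on_that_face(self):
        """chi{X^k + X^{k-1} >= 0}: only drift acts on a negative-sum face."""
        model = _diffusion_model(K=2)
        part = Partition.all_spde(2, alpha=1)
        hs = HybridState.from_compartment_counts(model, part, np.array([[0.0, 0.0]]))
        hs.grid[0, 0, 0] = -1.0
        hs.grid[0, 1, 0] = 0.5
        cfg = EMConfig(dt=1e-3, noise_on=True)

        class CountingRng:
            def __init__(self):
                self.inner = np.random.default_rng(0)

            def standard_normal(self, n):
                return np.full(n, 1e6)  # would be visible if amplitude nonzero

        out = em_step(hs, model, cfg, CountingRng())
        drift = 0.8 * 1e-3 / 1.0 * (0.5 - (-1.0))
        assert out.grid[0, 0, 0] == pytest.approx(-1.0 + drift)
        assert out.grid[0, 1, 0] == pytest.approx(0.5 - drift)

    def test_markov_cells_untouched(self, rng, morphogen):
        model, part = morphogen
        hs = HybridState.from_compartment_counts(model, part)
        out = em_step(hs, model, EMConfig(dt=5e-4), rng)
        assert np.array_equal(out.comp[0, 10:], hs.comp[0, 10:])

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            EMConfig(dt=0.0)


class TestNoiseOffEqualsDeterministicScheme:
    def test_kernel_matches_explicit_heat_step_oracle(self):
        """Without noise the stepper is the explicit finite-difference scheme."""
        K, alpha, D, dt = 4, 5, 0.8, 5e-4
        init = np.array([[200, 0, 40, 0]])
        model = _diffusion_model(K=K, init=init)
        part = Partition.all_spde(K, alpha=alpha)
        n_steps = 400
        traj = spde_only_run(model, part, t_end=n_steps * dt,
                             cfg=EMConfig(dt=dt, noise_on=False), seed=0,
                             record_times=[n_steps * dt], record_cells=True)
        # independent oracle: dense matrix iteration of the explicit scheme
        dx = 1.0 / alpha
        c = D * dt / dx ** 2
        x = np.repeat(init[0] / alpha, alpha).astype(float)
        for _ in range(n_steps):
            lap = np.zeros_like(x)
            lap[1:-1] = x[2:] - 2 * x[1:-1] + x[:-2]
            lap[0] = x[1] - x[0]
            lap[-1] = x[-2] - x[-1]
            x = x + c * lap
        assert np.allclose(traj.final_state.flat(), x, atol=1e-9)

    def test_numpy_reference_step_matches_kernel(self):
        """The readable em_step and the compiled loop agree exactly (no noise)."""
        K, alpha, dt = 3, 4, 1e-3
        init = np.array([[60, 0, 12]])
        model = _diffusion_model(K=K, init=init)
        part = Partition.all_spde(K, alpha=alpha)
        hs = HybridState.from_compartment_counts(model, part)
        cfg = EMConfig(dt=dt, noise_on=False)
        rng = np.random.default_rng(0)
        for _ in range(50):
            hs = em_step(hs, model, cfg, rng)
        traj = spde_only_run(model, part, t_end=50 * dt, cfg=cfg, seed=0,
                             record_times=[50 * dt], record_cells=True)
        assert np.allclose(traj.final_state.grid, hs.grid, atol=1e-12)


class TestSpdeOnlyRun:
    def test_zero_state_stays_zero(self):
        model = _diffusion_model(init=np.zeros((1, 4), dtype=int))
        part = Partition.all_spde(4, alpha=5)
        traj = spde_only_run(model, part, t_end=1.0, seed=1,
                             cfg=EMConfig(dt=1e-3))
        assert np.all(traj.counts == 0)

    def test_rejects_partition_with_markov_block(self, morphogen):
        model, part = morphogen
        with pytest.raises(ValueError, match="all-SPDE"):
            spde_only_run(model, part, t_end=0.1)

    def test_point_mass_variance_grows_like_2dt(self):
        """Second spatial moment of a spreading point mass ~ 2 D t."""
        K, alpha, D = 20, 2, 0.8
        init = np.zeros((1, K), dtype=int)
        init[0, K // 2] = 400
        model = _diffusion_model(K=K, D=D, init=init)
        part = Partition.all_spde(K, alpha=alpha)
        t_end = 2.0   # sqrt(2*D*t) ~ 1.8 µm << domain half-width: no boundary
        rs = RNGStream(7).realization_seeds(60)
        var = []
        sim = build_sim(model, part, em=EMConfig(dt=1e-3), t_end=t_end,
                        record_times=[t_end])
        dx = 1.0 / alpha
        centers = (np.arange(K * alpha) + 0.5) * dx
        x0 = (K // 2 + 0.5) * 1.0   # centre of the initially loaded compartment
        for s1, s2 in rs:
            raw = sim.run(s1, s2, record_cells=True)
            cells = raw["grid"][-1, 0].reshape(-1)
            w = cells / cells.sum()
            var.append(np.sum(w * (centers - x0) ** 2))
        mean_var = np.mean(var)
        assert mean_var == pytest.approx(2 * D * t_end, rel=0.15)

    def test_degradation_only_mean_decays_exponentially(self):
        dom = Domain.from_compartments(K=2, h=1.0)
        deg = ReactionSpec.first("deg", "S", {"S": -1}, 0.2)
        model = build_model(dom, [SpeciesSpec("S", 0.5)], [deg],
                            np.array([[150, 150]]))
        part = Partition.all_spde(2, alpha=4)
        n = 250
        rs = RNGStream(3).realization_seeds(n)
        sim = build_sim(model, part, em=EMConfig(dt=1e-3), t_end=5.0,
                        record_times=[5.0])
        totals = np.array([sim.run(s1, s2)["comp"][-1].sum() for s1, s2 in rs])
        expected = 300 * np.exp(-0.2 * 5.0)
        se = totals.std(ddof=1) / np.sqrt(n)
        assert abs(totals.mean() - expected) < 3 * se + 0.5
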