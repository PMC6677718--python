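"""Interface coupling: transfer rates, transfer mechanics, the coupled loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hybridrd import (Domain, EMConfig, HybridState, Partition, SchemeConfig,
                      SpeciesSpec, apply_transfer, build_model,
                      interface_propensities, run_hybrid, ssa_final_samples,
                      two_compartment_model)
from hybridrd.hybrid import build_sim
from hybridrd.core import RNGStream


def _state(two_comp):
    model, part = two_comp
    return model, part, HybridState.from_compartment_counts(model, part)


class TestInterfacePropensities:
    def test_psi_factors_printed_values(self):
        cfg = SchemeConfig(scheme="scheme2")
        psi1, psi2 = cfg.psi_values(h=1.0, dx=0.2)
        assert psi1 == pytest.approx(5 / 3)
        assert psi2 == pytest.approx(1 / 3)

    def test_equal_meshes_reduce_to_plain_jump_rates(self):
        """With dx = h, psi1 = psi2 = 1 and both schemes give D/h^2 * X."""
        model, part = two_compartment_model(alpha=1)
        hs = HybridState.from_compartment_counts(model, part,
                                                 np.array([[30.0, 20.0]]))
        for scheme in ("scheme1", "scheme2"):
            cfg = SchemeConfig(scheme=scheme)
            (entry,) = interface_propensities(hs, model, cfg)
            assert entry["m2s"] == pytest.approx(0.8 * 20.0)
            assert entry["s2m"] == pytest.approx(0.8 * 30.0)

    def test_pseudo_compartment_below_one_molecule_is_blocked(self, two_comp):
        model, part, hs = _state(two_comp)
        hs.grid[0, 0, :] = 0.07           # total 0.7 < 1
        (entry,) = interface_propensities(hs, model, SchemeConfig())
        assert entry["s2m"] == 0.0
        hs.grid[0, 0, :] = 0.11           # total 1.1 >= 1
        (entry,) = interface_propensities(hs, model, SchemeConfig())
        assert entry["s2m"] == pytest.approx(0.8 * 1.1)

    def test_scheme2_uses_edge_cell_only(self, two_comp):
        model, part, hs = _state(two_comp)
        hs.grid[0, 0, :] = 0.0
        hs.grid[0, 0, -1] = 2.0           # only the cell at the interface
        (entry,) = interface_propensities(hs, model, SchemeConfig("scheme2"))
        psi2 = 2 * 0.1 / 1.1
        assert entry["s2m"] == pytest.approx(psi2 * 0.8 / 0.1 ** 2 * 2.0)

    @given(st.floats(0.5, 3.0), st.integers(1, 30), st.floats(0.1, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_scheme2_flux_balance_at_uniform_concentration(self, h, alpha, conc):
        """At uniform concentration both transfer rates equal 2Dc·A/(dx+h)."""
        dx = h / alpha
        D = 0.8
        dom = Domain(L=2 * h, K=2, h=h)
        model = build_model(dom, [SpeciesSpec("S", D)], [],
                            np.zeros((1, 2), dtype=int))
        part = Partition.split(K_s=1, K=2, alpha=alpha)
        hs = HybridState.from_compartment_counts(model, part)
        hs.grid[0, 0, :] = conc * dx       # X per mesh cell (h_y = h_z = 1)
        hs.comp[0, 1] = conc * h
        (entry,) = interface_propensities(hs, model, SchemeConfig("scheme2"))
        expected = 2 * D * conc / (dx + h)
        assert entry["m2s"] == pytest.approx(expected, rel=1e-12)
        if conc * dx >= 1.0:               # the >=1 guard is part of the scheme
            assert entry["s2m"] == pytest.approx(expected, rel=1e-12)

    def test_kernel_and_reference_propensities_agree(self, morphogen):
        """The compiled propensity table matches the readable implementations."""
        from hybridrd import propensities
        model, part = morphogen
        rng = np.random.default_rng(8)
        for scheme in ("scheme1", "scheme2"):
            cfg = SchemeConfig(scheme)
            sim = build_sim(model, part, cfg, EMConfig(), t_end=1.0)
            hs = HybridState.from_compartment_counts(model, part)
            hs.grid[0, :10, :] = rng.normal(2.0, 1.5, size=(10, 5))
            hs.comp[0, 10:] = rng.integers(0, 40, size=10)
            prop, a0 = sim.debug_propensities(hs)
            K = 20
            # production fires only in compartment 1, which is SPDE here, so
            # it is handled by the Langevin terms: no SSA entry anywhere
            assert np.all(prop[0:K] == 0.0)
            # degradation: Langevin in the SPDE half, mass-action beyond
            assert np.all(prop[K:K + 10] == 0.0)
            assert np.allclose(prop[K + 10:2 * K], 0.05 * hs.comp[0, 10:])
            # plain Markov jumps at rate D/h^2 per molecule
            assert np.allclose(prop[2 * K + 11:3 * K], 0.8 * hs.comp[0, 11:])
            assert np.allclose(prop[3 * K + 10:4 * K - 1], 0.8 * hs.comp[0, 10:19])
            # no jump entries interior to the SPDE mesh (EM handles those)
            assert np.all(prop[2 * K:2 * K + 10] == 0.0)
            assert np.all(prop[3 * K:3 * K + 9] == 0.0)
            # interface entries equal the readable interface propensities
            (entry,) = interface_propensities(hs, model, cfg)
            assert prop[2 * K + 10] == pytest.approx(entry["m2s"])  # C11 leftward
            assert prop[3 * K + 9] == pytest.approx(entry["s2m"])   # C10 rightward
            assert a0 == pytest.approx(prop.sum(), rel=1e-12)


class TestApplyTransfer:
    def test_point_mode_places_molecule_uniformly(self, two_comp):
        model, part, hs = _state(two_comp)
        hs.comp[0, 1] = 10.0
        iface = hs.index_map().interfaces[0]
        cfg = SchemeConfig("scheme1", transfer_mode="point")
        rng = np.random.default_rng(15)
        counts = np.zeros(10)
        n = 4000
        for _ in range(n):
            out = apply_transfer(hs, iface, "S", "m2s", cfg, rng)
            gained = out.grid[0, 0, :] - hs.grid[0, 0, :]
            (cell,) = np.nonzero(gained)[0]
            assert gained[cell] == pytest.approx(1.0)
            counts[cell] += 1
        chi2 = ((counts - n / 10) ** 2 / (n / 10)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=9)

    def test_distributed_mode_spreads_fraction(self, two_comp):
        model, part, hs = _state(two_comp)
        hs.grid[0, 0, :] = 0.2
        iface = hs.index_map().interfaces[0]
        cfg = SchemeConfig("scheme1", transfer_mode="distributed")
        out = apply_transfer(hs, iface, "S", "s2m", cfg,
                             np.random.default_rng(0))
        assert np.allclose(out.grid[0, 0, :], 0.1)   # 0.2 - 1/10
        assert out.comp[0, 1] == hs.comp[0, 1] + 1

    @pytest.mark.parametrize("scheme,mode", [("scheme1", "point"),
                                             ("scheme1", "distributed"),
                                             ("scheme2", "point")])
    @pytest.mark.parametrize("direction", ["m2s", "s2m"])
    def test_total_mass_conserved(self, two_comp, scheme, mode, direction):
        model, part, hs = _state(two_comp)
        hs.comp[0, 1] = 7.0
        iface = hs.index_map().interfaces[0]
        cfg = SchemeConfig(scheme, transfer_mode=mode)
        out = apply_transfer(hs, iface, "S", direction, cfg,
                             np.random.default_rng(2))
        assert out.total() == pytest.approx(hs.total(), rel=1e-12)

    def test_empty_boundary_compartment_guarded(self, two_comp):
        model, part, hs = _state(two_comp)
        assert hs.comp[0, 1] == 0.0
        iface = hs.index_map().interfaces[0]
        out = apply_transfer(hs, iface, "S", "m2s", SchemeConfig(),
                             np.random.default_rng(0))
        assert out.total() == pytest.approx(hs.total())
        assert np.all(out.comp >= 0)


class TestRunHybrid:
    def test_mass_conserved_at_every_record_time(self, two_comp):
        model, part = two_comp
        for scheme in ("scheme1", "scheme2"):
            traj = run_hybrid(model, part, SchemeConfig(scheme), t_end=20.0,
                              em=EMConfig(dt=5e-4),
                              record_times=[0, 5, 10, 20], seed=9)
            assert np.allclose(traj.total(), 50.0, rtol=1e-9)

    def test_reproducible_given_seed(self, morphogen):
        model, part = morphogen
        kw = dict(t_end=1.0, em=EMConfig(dt=5e-4), record_times=[0.5, 1.0])
        a = run_hybrid(model, part, SchemeConfig(), seed=21, **kw)
        b = run_hybrid(model, part, SchemeConfig(), seed=21, **kw)
        c = run_hybrid(model, part, SchemeConfig(), seed=22, **kw)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    @pytest.mark.parametrize("scheme", ["scheme1", "scheme2"])
    def test_alpha_one_matches_full_ssa_distribution(self, scheme):
        """With alpha=1 both schemes are statistically the plain Markov chain."""
        model, part = two_compartment_model(alpha=1)
        n = 600
        t_end = 8.0   # several relaxation times 1/(2D/h^2)
        sim = build_sim(model, part, SchemeConfig(scheme), EMConfig(dt=5e-4),
                        t_end=t_end, record_times=[t_end])
        hyb = np.array([sim.run(s1, s2)["comp"][-1, 0, 1]
                        for s1, s2 in RNGStream(31).realization_seeds(n)])
        ssa = ssa_final_samples(model, t_end=t_end, n_realizations=n,
                                seed=32)[:, 0, 1]
        # two-sample comparison at the 1% level
        res = stats.ks_2samp(hyb, ssa)
        assert res.pvalue > 0.01


class TestScheme2EdgeGuard:
    def test_default_guard_blocks_negative_cells_only(self, two_comp):
        model, part, hs = _state(two_comp)
        hs.grid[0, 0, :] = 0.0
        hs.grid[0, 0, -1] = 0.4           # sub-molecule but positive
        (entry,) = interface_propensities(hs, model, SchemeConfig("scheme2"))
        psi2 = 2 * 0.1 / 1.1
        assert entry["s2m"] == pytest.approx(psi2 * 0.8 / 0.1 ** 2 * 0.4)
        hs.grid[0, 0, -1] = -0.4          # negative: no outgoing transfer
        (entry,) = interface_propensities(hs, model, SchemeConfig("scheme2"))
        assert entry["s2m"] == 0.0

    def test_strict_threshold_variant(self, two_comp):
        """edge_guard=1 refuses transfers from a sub-molecule edge cell."""
        model, part, hs = _state(two_comp)
        hs.grid[0, 0, :] = 0.0
        hs.grid[0, 0, -1] = 0.4
        cfg = SchemeConfig("scheme2", edge_guard=1.0)
        (entry,) = interface_propensities(hs, model, cfg)
        assert entry["s2m"] == 0.0
        hs.grid[0, 0, -1] = 1.4
        (entry,) = interface_propensities(hs, model, cfg)
        assert entry["s2m"] > 0.0

    def test_kernel_honours_configured_guard(self, two_comp):
        from hybridrd import EMConfig
        model, part, hs = _state(two_comp)
        hs.grid[0, 0, :] = 0.0
        hs.grid[0, 0, -1] = 0.4
        for guard in (0.0, 1.0):
            cfg = SchemeConfig("scheme2", edge_guard=guard)
            sim = build_sim(model, part, cfg, EMConfig(), t_end=1.0)
            prop, _ = sim.debug_propensities(hs)
            (entry,) = interface_propensities(hs, model, cfg)
            # no reactions: table is [left jumps k=1,2 | right jumps k=1,2]
            assert prop[1] == pytest.approx(entry["m2s"])   # C2 leftward
            assert prop[2] == pytest.approx(entry["s2m"])   # C1 rightward
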