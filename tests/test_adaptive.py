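"""Threshold-driven moving interface."""

import numpy as np
import pytest

from hybridrd import (AdaptiveConfig, EMConfig, HybridState, Partition,
                      SchemeConfig, check_and_move, run_adaptive, run_hybrid,
                      morphogen_model)


def _hybrid_state(model, K_s, alpha, counts=None):
    part = Partition.split(K_s=K_s, K=model.domain.K, alpha=alpha)
    return HybridState.from_compartment_counts(model, part, counts)


class TestCheckAndMove:
    def test_sparse_pseudo_compartment_reverts_to_markov(self, morphogen):
        model, _ = morphogen
        hs = _hybrid_state(model, K_s=10, alpha=5)
        hs.grid[0, 9, :] = 14.2 / 5        # pseudo-compartment total 14.2
        new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
        assert move == -1
        assert new.region[0, 9] == 0       # converted to Markov
        assert new.comp[0, 9] == 14.0      # rounded to the nearest integer
        assert np.all(new.grid[0, 9, :] == 0.0)

    def test_crowded_boundary_compartment_promoted_to_spde(self, morphogen):
        model, _ = morphogen
        hs = _hybrid_state(model, K_s=10, alpha=5)
        hs.grid[0, 9, :] = 4.0             # pseudo total 20 >= q_lower
        hs.comp[0, 10] = 30.0              # boundary count 30 > q_upper = 25
        new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
        assert move == +1
        assert new.region[0, 10] == 1
        assert np.allclose(new.grid[0, 10, :], 6.0)   # 30/alpha each
        assert new.comp[0, 10] == 0.0
        assert new.total() == pytest.approx(hs.total())

    def test_inside_window_no_move(self, morphogen):
        model, _ = morphogen
        hs = _hybrid_state(model, K_s=10, alpha=5)
        hs.grid[0, 9, :] = 4.0             # total 20
        hs.comp[0, 10] = 20.0
        new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
        assert move == 0
        assert np.array_equal(new.region, hs.region)

    def test_left_move_bounded_at_zero(self, morphogen):
        model, _ = morphogen
        zero = np.zeros((1, 20))
        hs = _hybrid_state(model, K_s=0, alpha=5, counts=zero)
        new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
        assert move == 0                   # no SPDE region: nothing to revert

    def test_all_markov_crowded_first_compartment_promoted(self, morphogen):
        model, _ = morphogen
        hs = _hybrid_state(model, K_s=0, alpha=5)   # 50 molecules in C1
        new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
        assert move == +1
        assert new.region[0, 0] == 1
        assert np.allclose(new.grid[0, 0, :], 10.0)

    def test_right_move_clamped_at_L_minus_h(self, morphogen):
        model, _ = morphogen
        hs = _hybrid_state(model, K_s=19, alpha=5)
        hs.grid[0, 18, :] = 10.0           # pseudo total >= q_lower
        hs.comp[0, 19] = 100.0             # would push interface past L-h
        new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
        assert move == 0
        assert new.region[0, 19] == 0

    def test_rounding_defect_bounded_by_half(self, morphogen):
        model, _ = morphogen
        for total in (14.2, 14.49, 14.51, 0.3):
            hs = _hybrid_state(model, K_s=10, alpha=5)
            hs.grid[0, 9, :] = total / 5
            new, move = check_and_move(hs, AdaptiveConfig(15, 25, 10))
            assert move == -1
            assert abs(new.total() - hs.total()) <= 0.5 + 1e-12


class TestRunAdaptive:
    def test_thresholds_disabled_equals_static_hybrid(self, morphogen):
        """q_lower=0, q_upper=inf: no moves, and huge n_c is also identical."""
        model, _ = morphogen
        alpha = 5
        common = dict(alpha=alpha, t_end=2.0, em=EMConfig(dt=5e-4),
                      record_times=[1.0, 2.0], seed=77,
                      scheme_cfg=SchemeConfig(transfer_mode="distributed"))
        a = run_adaptive(model, AdaptiveConfig(0.0, np.inf, 10,
                                               initial_interface=10.0), **common)
        b = run_adaptive(model, AdaptiveConfig(15.0, 25.0, 10 ** 9,
                                               initial_interface=10.0), **common)
        assert np.array_equal(a.counts, b.counts)
        assert np.all(a.interface == 10.0)

    def test_frozen_interface_matches_static_hybrid_distribution(self, morphogen):
        """With moves disabled the adaptive loop reproduces the static run."""
        from hybridrd import run_ensemble
        model, _ = morphogen
        alpha, t_end, n = 5, 2.0, 80
        part = Partition.split(10, model.domain.K, alpha)
        cfg = SchemeConfig(transfer_mode="distributed")
        adap = run_ensemble(model, part, cfg, EMConfig(dt=5e-4), t_end=t_end,
                            record_times=[t_end], n_realizations=n, seed=11,
                            adaptive=AdaptiveConfig(0.0, np.inf, 10,
                                                    initial_interface=10.0))
        stat = run_ensemble(model, part, cfg, EMConfig(dt=5e-4), t_end=t_end,
                            record_times=[t_end], n_realizations=n, seed=12)
        se = np.sqrt(adap.sd[-1] ** 2 + stat.sd[-1] ** 2) / np.sqrt(n)
        assert np.all(np.abs(adap.mean[-1] - stat.mean[-1]) < 4 * se + 0.5)

    def test_interface_stays_on_compartment_grid(self, morphogen):
        model, _ = morphogen
        traj = run_adaptive(model, AdaptiveConfig(15, 25, 10), alpha=5,
                            t_end=5.0, em=EMConfig(dt=5e-4),
                            record_times=np.linspace(0, 5, 11), seed=5,
                            state0=None)
        h, L = model.domain.h, model.domain.L
        assert np.all(traj.interface >= 0)
        assert np.all(traj.interface <= L)
        assert np.allclose(traj.interface / h, np.round(traj.interface / h))

    def test_gradient_buildup_moves_interface_right(self, morphogen):
        """From the empty state the interface tracks the forming gradient."""
        model, _ = morphogen
        zero = np.zeros((1, 20))
        n_up = 0
        n = 20
        for seed in range(n):
            part0 = Partition.split(0, 20, 5)
            state0 = HybridState.from_compartment_counts(model, part0, zero)
            traj = run_adaptive(model, AdaptiveConfig(15, 25, 10), alpha=5,
                                t_end=20.0, em=EMConfig(dt=5e-4),
                                record_times=[5.0, 20.0], seed=seed,
                                state0=state0)
            if traj.interface[-1] >= traj.interface[0] and traj.interface[-1] >= 2.0:
                n_up += 1
        assert n_up >= int(0.7 * n)

    def test_point_transfer_mode_is_replaced_for_scheme1(self, morphogen):
        """Adaptive Scheme 1 runs always use distributed transfers."""
        model, _ = morphogen
        traj = run_adaptive(model, AdaptiveConfig(15, 25, 10), alpha=5,
                            t_end=0.5, em=EMConfig(dt=5e-4),
                            scheme_cfg=SchemeConfig("scheme1", "point"), seed=1)
        assert traj.counts.shape[2] == 20   # ran without error
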