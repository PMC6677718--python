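"""Exact Gillespie SSA for the full compartment-based model.

Diffusion of species i between neighbouring compartments is a jump process
at per-molecule rate D_i/h²; reactions fire with their mass-action
propensities.  The direct method draws the waiting time tau = -log(r1)/a0
from the total propensity a0 and selects the event with probability
proportional to its propensity, in a fixed enumeration order (reactions by
j then k, then left jumps, then right jumps) so trajectories are
reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import CompiledSim
from .core import HybridState, Partition, ReactionDiffusionModel, RNGStream
from .results import Trajectory
from .spde import _traj_from_raw


@dataclass
class PropensityTable:
    """Reaction and diffusion propensities of a Markov-chain state.

    ``a_minus[i, k]`` is the rate of a jump of species i from compartment
    k+1 to k (0 at the left boundary); ``a_plus[i, k]`` toward k+2 (0 at the
    right boundary).  ``a0`` is the total.
    """

    a_react: np.ndarray   # (M, K)
    a_minus: np.ndarray   # (N, K)
    a_plus: np.ndarray    # (N, K)

    @property
    def a0(self) -> float:
        return float(self.a_react.sum() + self.a_minus.sum() + self.a_plus.sum())


def propensities(model: ReactionDiffusionModel, state: np.ndarray) -> PropensityTable:
    """Propensity table for integer per-compartment counts ``state`` (N, K)."""
    z = np.asarray(state, dtype=float)
    K, N, M = model.domain.K, model.n_species, len(model.reactions)
    if z.shape != (N, K):
        raise ValueError(f"state must have shape (N={N}, K={K})")
    if np.any(z < 0):
        raise ValueError("Markov state must be non-negative")
    a_react = np.zeros((M, K))
    for j, r in enumerate(model.reactions):
        for k in range(1, K + 1):
            counts = {name: z[model.species_index(name), k - 1]
                      for name in model.species_names}
            a_react[j, k - 1] = r.propensity(k, counts, K)
    jump = np.array([model.jump_rate(i) for i in range(N)])[:, None]
    a_minus = jump * z
    a_minus[:, 0] = 0.0          # no outward diffusion at the left boundary
    a_plus = jump * z
    a_plus[:, -1] = 0.0          # nor at the right boundary
    return PropensityTable(a_react, a_minus, a_plus)


def ssa_run(model: ReactionDiffusionModel, state0: np.ndarray | None = None,
            t_end: float = 1.0, record_times=None, seed: int = 0) -> Trajectory:
    """Statistically exact sample path of the compartment-based model.

    If the total propensity reaches zero the state is absorbing and the
    remaining record times repeat it.
    """
    K = model.domain.K
    part = Partition.all_markov(K)
    if state0 is None:
        counts = None
    else:
        counts = np.asarray(state0, dtype=float)
        if np.any(counts < 0) or not np.array_equal(counts, np.round(counts)):
            raise ValueError("state0 must be non-negative integers")
    hs = HybridState.from_compartment_counts(model, part, counts)
    sim = CompiledSim(model, hs, dt=1.0, t_end=t_end, record_times=record_times)
    ssa_seed, noise_seed = RNGStream(seed).single()
    raw = sim.run(ssa_seed, noise_seed)
    return _traj_from_raw(raw, model, False)


def ssa_final_samples(model: ReactionDiffusionModel, t_end: float,
                      n_realizations: int, seed: int = 0,
                      state0: np.ndarray | None = None) -> np.ndarray:
    """Per-realization compartment counts at t_end, shape (n, N, K)."""
    K = model.domain.K
    part = Partition.all_markov(K)
    counts = None if state0 is None else np.asarray(state0, dtype=float)
    hs = HybridState.from_compartment_counts(model, part, counts)
    sim = CompiledSim(model, hs, dt=1.0, t_end=t_end)
    out = np.empty((n_realizations, model.n_species, K))
    for r, (s1, s2) in enumerate(RNGStream(seed).realization_seeds(n_realizations)):
        out[r] = sim.run(s1, s2)["comp"][-1]
    return out
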