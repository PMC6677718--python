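"""Moving-interface extension of the hybrid algorithm.

The interface I(t) between the SPDE region (left) and the Markov region
(right) is re-examined every ``n_c`` EM steps: if the pseudo-compartment's
total mesh mass has dropped below ``q_lower`` that compartment reverts to the
Markov description (mesh mass summed and rounded to the nearest integer);
otherwise, if the boundary Markov compartment holds more than ``q_upper``
molecules it is promoted to the SPDE description with its molecules
redistributed uniformly over the alpha mesh cells.  At most one move of +-h
happens per check and the interface stays within [0, L-h].  Adaptive runs
use the distributed transfer mode of Scheme 1 (+-1/alpha on every cell of
the pseudo-compartment); with point transfers the gradient fails to form
once the interface starts moving.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (MARKOV, SPDE, HybridState, Partition,
                   ReactionDiffusionModel, RNGStream)
from .hybrid import SchemeConfig, build_sim
from .results import Trajectory
from .spde import EMConfig, _traj_from_raw


@dataclass(frozen=True)
class AdaptiveConfig:
    """Thresholds (molecules), check interval (EM steps) and I(0) (µm)."""

    q_lower: float = 15.0
    q_upper: float = 25.0
    n_c: int = 10
    initial_interface: float = 0.0

    def __post_init__(self) -> None:
        if self.q_upper < self.q_lower:
            raise ValueError("q_upper must be >= q_lower")
        if self.n_c < 1:
            raise ValueError("n_c must be a positive integer")


def check_and_move(state: HybridState, acfg: AdaptiveConfig) -> tuple[HybridState, int]:
    """One interface check on a single-species state.

    Returns the (possibly converted) state and the move direction:
    -1 (SPDE->Markov, interface moved left by h), +1 (Markov->SPDE, moved
    right by h) or 0 (no move).
    """
    if len(state.species_names) != 1:
        raise ValueError("the adaptive interface supports single-species models")
    new = state.copy()
    K, A = state.region.shape[1], state.alpha
    ks = 0
    while ks < K and state.region[0, ks] == SPDE:
        ks += 1
    if ks > 0:
        tot = float(state.grid[0, ks - 1, :].sum())
        if tot < acfg.q_lower:
            new.comp[0, ks - 1] = max(np.rint(tot), 0.0)
            new.grid[0, ks - 1, :] = 0.0
            new.region[0, ks - 1] = MARKOV
            return new, -1
        if ks < K and state.comp[0, ks] > acfg.q_upper:
            if ks >= K - 1:
                return new, 0  # clamped: interface may not pass L-h
            new.grid[0, ks, :] = state.comp[0, ks] / A
            new.comp[0, ks] = 0.0
            new.region[0, ks] = SPDE
            return new, +1
        return new, 0
    if state.comp[0, 0] > acfg.q_upper and K >= 2:
        new.grid[0, 0, :] = state.comp[0, 0] / A
        new.comp[0, 0] = 0.0
        new.region[0, 0] = SPDE
        return new, +1
    return new, 0


def run_adaptive(model: ReactionDiffusionModel, acfg: AdaptiveConfig,
                 scheme_cfg: SchemeConfig = SchemeConfig(), alpha: int = 5,
                 t_end: float = 1.0, em: EMConfig = EMConfig(),
                 record_times=None, seed: int = 0,
                 state0: HybridState | None = None,
                 record_cells: bool = False) -> Trajectory:
    """Hybrid run with the threshold-driven moving interface.

    The returned trajectory carries the interface path I(t) (µm) at the
    record times.  By default the run starts fully compartment-based
    (I(0) = 0) from the model's initial counts.
    """
    if scheme_cfg.scheme == "scheme1":
        scheme_cfg = replace(scheme_cfg, transfer_mode="distributed")
    K, h = model.domain.K, model.domain.h
    ks0 = int(round(acfg.initial_interface / h))
    if not 0 <= ks0 <= K - 1:
        raise ValueError("initial interface must lie in [0, L-h]")
    partition = Partition.split(ks0, K, alpha)
    if state0 is None:
        state0 = HybridState.from_compartment_counts(model, partition)
    sim = build_sim(model, partition, scheme_cfg, em, t_end, record_times,
                    state0, adaptive=acfg)
    ssa_seed, noise_seed = RNGStream(seed).single()
    raw = sim.run(ssa_seed, noise_seed, record_cells=record_cells)
    return _traj_from_raw(raw, model, record_cells)
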