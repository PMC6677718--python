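"""Hybrid event loop coupling the Markov region with the SPDE region.

Two interface couplings are provided.  Scheme 1 treats the compartment-sized
strip of the SPDE mesh next to the interface as a *pseudo-compartment*: a
molecule jumps from the boundary Markov compartment into a uniformly chosen
mesh cell of the pseudo-compartment at per-molecule rate D/h², and leaves the
pseudo-compartment (total mass summed over its alpha cells, guarded to be at
least 1) at rate D/h² toward the boundary compartment.  Scheme 2 has no
overlap: transfers happen between the last mesh cell and the boundary
compartment with finite-volume-matched rates Ψ1 D/h² and Ψ2 D/dx², where
Ψ1 = 2h/(dx+h) and Ψ2 = 2dx/(dx+h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import CompiledSim
from .core import (HybridState, Interface, Partition,
                   ReactionDiffusionModel, RNGStream)
from .results import Trajectory
from .spde import EMConfig, _traj_from_raw


@dataclass(frozen=True)
class SchemeConfig:
    """Interface-coupling choice and its parameters.

    ``transfer_mode`` applies to Scheme 1 only: ``point`` moves +-1 molecule
    at one uniformly chosen mesh cell of the pseudo-compartment, while
    ``distributed`` spreads +-1/alpha over all its cells (the variant the
    moving-interface algorithm requires).  ``psi1``/``psi2`` default to the
    finite-volume-matched values and lie in (0, 2).

    ``edge_guard`` is the Scheme 2 outgoing-transfer threshold: the
    SPDE->Markov propensity is zero while the edge mesh cell holds less than
    this many molecules.  The default 0 only forbids negative propensities;
    it keeps the mean outgoing flux near the finite-volume value and
    reproduces the documented accuracy of Scheme 2 on coarse-to-moderate
    meshes and its over-transfer bias on fine ones.  A strict threshold of 1
    (refuse to transfer unless a whole molecule is present, so the transfer
    itself cannot drive the cell negative) truncates the mean flux whenever
    the edge cell averages below ~1 molecule and severely starves the Markov
    side at fine meshes; it is provided for sensitivity analysis.

    Interface and reaction propensities in the Markov loop depend on SPDE
    mesh values, which change at every EM update.  By default
    (``redraw_after_spde=True``) the pending event time is therefore redrawn
    after each EM step — a memoryless refresh that samples the
    piecewise-constant time-varying rates exactly.  Setting it to ``False``
    keeps the event clock and selection frozen between Markov events, as the
    published pseudocode is literally written; for couplings whose transfer
    rate tracks a single fluctuating mesh cell (Scheme 2 at fine meshes) the
    frozen clock badly under-samples the transfer and cannot reproduce the
    documented interface bias, so it is exposed only for sensitivity checks.
    """

    scheme: str = "scheme1"
    transfer_mode: str = "point"
    psi1: float | None = None
    psi2: float | None = None
    edge_guard: float = 0.0
    redraw_after_spde: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("scheme1", "scheme2"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.transfer_mode not in ("point", "distributed"):
            raise ValueError(f"unknown transfer_mode {self.transfer_mode!r}")

    def psi_values(self, h: float, dx: float) -> tuple[float, float]:
        psi1 = self.psi1 if self.psi1 is not None else 2 * h / (dx + h)
        psi2 = self.psi2 if self.psi2 is not None else 2 * dx / (dx + h)
        if not (0 < psi1 < 2 and 0 < psi2 < 2):
            raise ValueError("psi factors must lie in (0, 2)")
        return psi1, psi2


def interface_propensities(state: HybridState, model: ReactionDiffusionModel,
                           cfg: SchemeConfig) -> list[dict]:
    """Per-interface, per-species transfer rates (markov->spde, spde->markov)."""
    h = model.domain.h
    dx = h / state.alpha
    psi1, psi2 = cfg.psi_values(h, dx)
    out = []
    for i, name in enumerate(state.species_names):
        imap = state.index_map(i)
        for iface in imap.interfaces:
            km = iface.boundary_compartment - 1
            ks = iface.pseudo_compartment - 1
            D = model.species[i].D
            m2s = D / h ** 2 * state.comp[i, km]
            if cfg.scheme == "scheme2":
                m2s *= psi1
                edge = state.alpha - 1 if iface.spde_side == "left" else 0
                x = state.grid[i, ks, edge]
                s2m = (psi2 * D / dx ** 2 * x
                       if x >= cfg.edge_guard else 0.0)
            else:
                tot = state.grid[i, ks, :].sum()
                s2m = D / h ** 2 * tot if tot >= 1.0 else 0.0
            out.append({"interface": iface, "species": name,
                        "m2s": float(m2s), "s2m": float(s2m)})
    return out


def apply_transfer(state: HybridState, interface: Interface,
                   species: int | str, direction: str, cfg: SchemeConfig,
                   rng: np.random.Generator) -> HybridState:
    """Apply one fired interface transfer; total copy number is conserved."""
    if direction not in ("m2s", "s2m"):
        raise ValueError("direction must be 'm2s' or 's2m'")
    new = state.copy()
    i = state._idx(species)
    A = state.alpha
    km = interface.boundary_compartment - 1
    ks = interface.pseudo_compartment - 1
    sign = 1.0 if direction == "m2s" else -1.0
    if direction == "m2s":
        if new.comp[i, km] < 0.5:
            return new  # guard: nothing to transfer
        new.comp[i, km] -= 1.0
    else:
        new.comp[i, km] += 1.0
    if cfg.scheme == "scheme2":
        if interface.spde_side == "left":
            ell = A - 1
        else:
            ell = 0
        new.grid[i, ks, ell] += sign
    elif cfg.transfer_mode == "point":
        ell = min(int(rng.random() * A), A - 1)
        new.grid[i, ks, ell] += sign
    else:
        new.grid[i, ks, :] += sign / A
    return new


def build_sim(model: ReactionDiffusionModel, partition: Partition,
              cfg: SchemeConfig = SchemeConfig(), em: EMConfig = EMConfig(),
              t_end: float = 1.0, record_times=None,
              state0: HybridState | None = None, adaptive=None) -> CompiledSim:
    """Compile a (model, partition, scheme) triple for the fast event loop."""
    if state0 is None:
        state0 = HybridState.from_compartment_counts(model, partition)
    h = model.domain.h
    psi1, psi2 = cfg.psi_values(h, h / partition.alpha)
    return CompiledSim(model, state0, scheme=cfg.scheme,
                       transfer_mode=cfg.transfer_mode,
                       psi1=psi1, psi2=psi2, edge_guard=cfg.edge_guard,
                       noise_on=em.noise_on,
                       redraw_after_spde=cfg.redraw_after_spde,
                       dt=em.dt, t_end=t_end, record_times=record_times,
                       adaptive=adaptive)


def run_hybrid(model: ReactionDiffusionModel, partition: Partition,
               cfg: SchemeConfig = SchemeConfig(), t_end: float = 1.0,
               em: EMConfig = EMConfig(), record_times=None, seed: int = 0,
               state0: HybridState | None = None,
               record_cells: bool = False) -> Trajectory:
    """One realization of the coupled SSA/SPDE loop with a static interface."""
    sim = build_sim(model, partition, cfg, em, t_end, record_times, state0)
    ssa_seed, noise_seed = RNGStream(seed).single()
    raw = sim.run(ssa_seed, noise_seed, record_cells=record_cells)
    return _traj_from_raw(raw, model, record_cells)
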