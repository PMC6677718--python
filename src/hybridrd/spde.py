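"""Euler–Maruyama stepper for the spatially discretized SPDE.

The diffusion part of the update applies, to every interior mesh face, a
drift ``D dt/dx² (X^k - X^{k-1})`` and a single shared Gaussian increment of
variance ``D dt/dx² (X^k + X^{k-1})`` guarded by the pair-sum indicator, with
opposite signs on the two cells — so the diffusion operator conserves mass
exactly, step by step.  Reactions whose participating species are all
represented by the SPDE in a compartment contribute a cell-local Langevin
term: drift ``lambda_cell dt`` and noise ``sqrt(max(lambda_cell, 0) dt)``
times the stoichiometry, where ``lambda_cell`` is the propensity evaluated on
the cell contents (for zeroth order, the compartment rate split over the
cells, or concentrated in the first cell for a boundary-flux source).

Negative cell values are permitted and never clamped; only noise amplitudes
are guarded.  The ``noise_on=False`` variant drops every stochastic term and
reduces the stepper to the explicit finite-difference scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .core import SPDE, HybridState, Partition, ReactionDiffusionModel
from .results import Trajectory


@dataclass(frozen=True)
class EMConfig:
    """Euler–Maruyama configuration: fixed step ``dt`` (s) and noise switch."""

    dt: float = 5e-4
    noise_on: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _langevin_mode(model: ReactionDiffusionModel, region: np.ndarray) -> np.ndarray:
    """mode[j,k] True where reaction j is simulated by the Langevin terms."""
    M, K = len(model.reactions), model.domain.K
    mode = np.zeros((M, K), dtype=bool)
    for j, r in enumerate(model.reactions):
        if r.order >= 2 or not r.involved:
            continue
        rows = [model.species_index(s) for s in r.involved]
        mode[j] = np.all(region[rows] == SPDE, axis=0)
    return mode


def em_step(state: HybridState, model: ReactionDiffusionModel,
            cfg: EMConfig, rng: np.random.Generator) -> HybridState:
    """One EM step of the SPDE cells; Markov cells are left untouched.

    This is the readable reference implementation; the production loop uses
    the compiled kernel, which is cross-checked against this one in tests.
    """
    new = state.copy()
    region, grid = state.region, state.grid
    N, K, A = grid.shape
    dx = model.domain.h / A
    dt = cfg.dt

    for i in range(N):
        c = model.species[i].D * dt / dx ** 2
        spde_k = np.flatnonzero(region[i] == SPDE)
        if spde_k.size == 0:
            continue
        # contiguous runs of SPDE compartments share a mesh
        breaks = np.flatnonzero(np.diff(spde_k) > 1)
        for run in np.split(spde_k, breaks + 1):
            x = grid[i, run, :].reshape(-1)
            F = c * np.diff(x)
            if cfg.noise_on:
                s = x[1:] + x[:-1]
                amp = np.sqrt(c * np.where(s >= 0, s, 0.0)) * (s >= 0)
                F = F + amp * rng.standard_normal(F.size)
            xn = x.copy()
            xn[1:] -= F
            xn[:-1] += F
            new.grid[i, run, :] = xn.reshape(len(run), A)

    mode = _langevin_mode(model, region)
    for j, r in enumerate(model.reactions):
        stoich_rows = [(model.species_index(s), z) for s, z in r.stoich.items() if z]
        for k in np.flatnonzero(mode[j]):
            rate_k = r.rate_in(k + 1, K)
            if r.order == 0:
                lam = np.zeros(A)
                if r.spde_placement == "first_cell":
                    lam[0] = rate_k
                else:
                    lam[:] = rate_k / A
            else:
                s1 = model.species_index(r.reactants[0])
                lam = rate_k * grid[s1, k, :]
            d = lam * dt
            if cfg.noise_on:
                d = d + np.sqrt(np.clip(lam, 0, None) * dt) * rng.standard_normal(A)
            for i, z in stoich_rows:
                new.grid[i, k, :] += z * d
    new.t = state.t + dt
    return new


def spde_only_run(model: ReactionDiffusionModel, partition: Partition,
                  state0: HybridState | None = None, t_end: float = 1.0,
                  cfg: EMConfig = EMConfig(), seed: int = 0,
                  record_times=None, record_cells: bool = False) -> Trajectory:
    """Pure SPDE simulation: the partition must be a single SPDE block."""
    from .core import RNGStream
    K = model.domain.K
    if np.any(partition.region_array(K) != SPDE):
        raise ValueError("spde_only_run requires an all-SPDE partition")
    if state0 is None:
        state0 = HybridState.from_compartment_counts(model, partition)
    sim = _kernel.CompiledSim(model, state0, noise_on=cfg.noise_on,
                              dt=cfg.dt, t_end=t_end, record_times=record_times)
    ssa_seed, noise_seed = RNGStream(seed).single()
    raw = sim.run(ssa_seed, noise_seed, record_cells=record_cells)
    return _traj_from_raw(raw, model, record_cells)


def _traj_from_raw(raw: dict, model: ReactionDiffusionModel,
                   record_cells: bool) -> Trajectory:
    states = None
    if record_cells:
        states = [HybridState(model.species_names, raw["region"][r],
                              raw["grid"].shape[3], raw["compraw"][r],
                              raw["grid"][r], t=raw["times"][r])
                  for r in range(len(raw["times"]))]
    d = raw["diag"]
    return Trajectory(
        times=raw["times"], counts=raw["comp"],
        species_names=model.species_names,
        interface=raw["ks"].astype(float) * model.domain.h,
        states=states,
        diagnostics={"n_conversions_spde_to_markov": int(d[0]),
                     "n_conversions_markov_to_spde": int(d[1]),
                     "rounding_mass_defect": float(d[2]),
                     "n_clamped_moves": int(d[3])},
    )
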