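"""Trajectory and ensemble-summary containers with tidy CSV export."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HybridState


@dataclass
class Trajectory:
    """States of one realization sampled at ``times``.

    ``counts`` holds compartment-aggregated copy numbers (SPDE mesh cells of
    a compartment summed), shape ``(n_times, n_species, K)``.  ``interface``
    is the interface position I(t) in µm (leading SPDE compartments times h);
    it is constant for static partitions.
    """

    times: np.ndarray
    counts: np.ndarray
    species_names: tuple[str, ...]
    interface: np.ndarray | None = None
    states: list[HybridState] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def final_state(self) -> HybridState | None:
        return self.states[-1] if self.states else None

    def total(self, species: int | str | None = None) -> np.ndarray:
        """Total copy number over the whole domain at each record time."""
        if species is None:
            return self.counts.sum(axis=(1, 2))
        i = (self.species_names.index(species)
             if isinstance(species, str) else species)
        return self.counts[:, i, :].sum(axis=1)

    def to_frame(self, realization: int = 0) -> pd.DataFrame:
        """Tidy frame (realization, time, species, compartment, count)."""
        n_t, N, K = self.counts.shape
        return pd.DataFrame({
            "realization": realization,
            "time": np.repeat(self.times, N * K),
            "species": np.tile(np.repeat(self.species_names, K), n_t),
            "compartment": np.tile(np.arange(1, K + 1), n_t * N),
            "count": self.counts.ravel(),
        })


@dataclass
class EnsembleSummary:
    """Per-compartment mean and standard deviation over realizations.

    SPDE mesh cells are aggregated per compartment within each realization
    before the statistics are taken, so ``sd`` is the standard deviation of
    the per-compartment totals.  ``final_samples`` keeps the per-realization
    compartment counts at the last record time for distribution-level checks.
    """

    times: np.ndarray
    species_names: tuple[str, ...]
    mean: np.ndarray                      # (n_times, N, K)
    sd: np.ndarray                        # (n_times, N, K)
    n_realizations: int
    final_samples: np.ndarray | None = None   # (n_real, N, K)
    totals: np.ndarray | None = None          # (n_real, n_times)
    interface: np.ndarray | None = None       # (n_real, n_times), µm

    def at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) arrays of shape (N, K) at the record time closest to t."""
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.mean[idx], self.sd[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame (time, species, compartment, mean, sd)."""
        n_t, N, K = self.mean.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, N * K),
            "species": np.tile(np.repeat(self.species_names, K), n_t),
            "compartment": np.tile(np.arange(1, K + 1), n_t * N),
            "mean": self.mean.ravel(),
            "sd": self.sd.ravel(),
        })
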