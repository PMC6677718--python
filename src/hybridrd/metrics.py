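"""Relative-error functionals against the Markov-chain reference.

For each compartment k the multiscale ensemble is compared to the reference
mean E[Z^k] and standard deviation sigma[Z^k] through

    e_m(k) = 1 - E[sum of the compartment's cells] / E[Z^k],
    e_v(k) = 1 - sigma[sum of the compartment's cells] / sigma[Z^k],

where SPDE compartments aggregate their alpha mesh cells (within each
realization) before the statistics are taken.  Compartments whose reference
mean or sd is zero are reported as undefined (NaN) and excluded from the
maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moments import MomentSolution
from .results import EnsembleSummary


@dataclass
class ErrorReport:
    """Per-compartment relative errors and their maxima over the domain."""

    e_m: np.ndarray   # (N, K), NaN where undefined
    e_v: np.ndarray   # (N, K)

    @property
    def max_abs_e_m(self) -> float:
        return float(np.nanmax(np.abs(self.e_m)))

    @property
    def max_abs_e_v(self) -> float:
        return float(np.nanmax(np.abs(self.e_v)))

    @property
    def max_abs(self) -> float:
        return max(self.max_abs_e_m, self.max_abs_e_v)


def relative_errors_arrays(ens_mean: np.ndarray, ens_sd: np.ndarray,
                           ref_mean: np.ndarray, ref_sd: np.ndarray) -> ErrorReport:
    """Error report from (N, K) compartment-level statistics."""
    with np.errstate(divide="ignore", invalid="ignore"):
        e_m = np.where(ref_mean > 0, 1.0 - ens_mean / ref_mean, np.nan)
        e_v = np.where(ref_sd > 0, 1.0 - ens_sd / ref_sd, np.nan)
    if np.all(np.isnan(e_m)) or np.all(np.isnan(e_v)):
        raise ValueError("reference mean/sd are zero everywhere: errors undefined")
    return ErrorReport(e_m=e_m, e_v=e_v)


def relative_errors(ensemble: EnsembleSummary, reference: MomentSolution,
                    t: float | None = None) -> ErrorReport:
    """Compare an ensemble summary with the analytic moments at time ``t``.

    The ensemble is already compartment-aggregated (the summary sums a
    compartment's SPDE mesh cells within each realization), so any split of
    mass among the alpha cells of a compartment leaves the result unchanged.
    """
    if t is None:
        t = float(ensemble.times[-1])
    em, es = ensemble.at(t)
    rm, rs = reference.at(t)
    if not np.isclose(ensemble.times[np.argmin(np.abs(ensemble.times - t))],
                      reference.times[np.argmin(np.abs(reference.times - t))],
                      atol=1e-9):
        raise ValueError("ensemble and reference were not recorded at time t")
    return relative_errors_arrays(em, es, rm, rs)
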