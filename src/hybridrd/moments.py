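"""Analytic moment oracle for linear reaction–diffusion networks.

For a Markov jump process whose transition propensities are affine in the
state — every reaction of order 0 or 1, plus diffusion jumps, which are
first-order in the donor compartment — the mean vector m(t) and covariance
matrix C(t) obey the closed linear ODEs

    dm/dt = A m + b,
    dC/dt = A C + C Aᵀ + B(m),     B(m) = Σ_r ζ_r ζ_rᵀ λ_r(m),

where the sum runs over all transitions r with jump vector ζ_r and affine
propensity λ_r(z) = c_r + w_rᵀ z, A = Σ_r ζ_r w_rᵀ and b = Σ_r ζ_r c_r.
These are integrated with a stiff-capable solver at tight tolerance so the
oracle error is negligible against Monte-Carlo error.  A brute-force
enumerator of the truncated master equation is provided for tiny systems as
an independent check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import expm_multiply, spsolve

from .core import ReactionDiffusionModel


@dataclass
class MomentSolution:
    """Mean and standard deviation per (species, compartment) over time."""

    times: np.ndarray
    mean: np.ndarray   # (n_times, N, K)
    sd: np.ndarray     # (n_times, N, K)

    def at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.mean[idx], self.sd[idx]


def _transitions(model: ReactionDiffusionModel):
    """All affine transitions as (zeta, c0, w) over the flat state (N*K)."""
    K, N = model.domain.K, model.n_species
    n = N * K

    def sidx(i, k):
        return i * K + k

    out = []
    for r in model.reactions:
        if r.order > 1:
            raise ValueError(
                f"reaction {r.name!r} has order {r.order}: "
                "moments do not close for nonlinear propensities")
        for k in range(K):
            rate = r.rate_in(k + 1, K)
            if rate == 0:
                continue
            zeta = np.zeros(n)
            for name, z in r.stoich.items():
                zeta[sidx(model.species_index(name), k)] = z
            w = np.zeros(n)
            c0 = 0.0
            if r.order == 0:
                c0 = rate
            else:
                w[sidx(model.species_index(r.reactants[0]), k)] = rate
            out.append((zeta, c0, w))
    for i in range(N):
        q = model.jump_rate(i)
        if q == 0:
            continue
        for k in range(K - 1):
            for src, dst in ((k, k + 1), (k + 1, k)):
                zeta = np.zeros(n)
                zeta[sidx(i, src)] = -1
                zeta[sidx(i, dst)] = 1
                w = np.zeros(n)
                w[sidx(i, src)] = q
                out.append((zeta, 0.0, w))
    return out


def analytic_moments(model: ReactionDiffusionModel, t_grid) -> MomentSolution:
    """Exact mean/sd of the full Markov-chain model on ``t_grid``.

    Requires every reaction to have order <= 1.  The initial condition is the
    model's deterministic initial state (zero covariance).
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    K, N = model.domain.K, model.n_species
    n = N * K
    trans = _transitions(model)
    A = np.zeros((n, n))
    b = np.zeros(n)
    B_const = np.zeros((n, n))
    B_lin = np.zeros((n, n, n))
    for zeta, c0, w in trans:
        A += np.outer(zeta, w)
        b += zeta * c0
        zz = np.outer(zeta, zeta)
        B_const += zz * c0
        B_lin += zz[:, :, None] * w[None, None, :]

    m0 = model.init.astype(float).reshape(n)
    y0 = np.concatenate([m0, np.zeros(n * n)])

    def rhs(_t, y):
        m = y[:n]
        C = y[n:].reshape(n, n)
        dm = A @ m + b
        dC = A @ C + C @ A.T + B_const + B_lin @ m
        return np.concatenate([dm, dC.ravel()])

    t0, t1 = 0.0, float(t_grid[-1]) if t_grid[-1] > 0 else 0.0
    if t1 == 0.0:
        ms = np.tile(m0, (len(t_grid), 1))
        Cs = np.zeros((len(t_grid), n, n))
    else:
        sol = solve_ivp(rhs, (t0, t1), y0, t_eval=t_grid, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"moment ODE integration failed: {sol.message}")
        ms = sol.y[:n].T
        Cs = sol.y[n:].T.reshape(len(t_grid), n, n)
    var = np.clip(np.diagonal(Cs, axis1=1, axis2=2), 0.0, None)
    return MomentSolution(times=t_grid,
                         mean=ms.reshape(len(t_grid), N, K),
                         sd=np.sqrt(var).reshape(len(t_grid), N, K))


# ---------------------------------------------------------------------------
# Brute-force master-equation enumeration (tiny systems)
# ---------------------------------------------------------------------------

class CMEDistribution:
    """Exact distribution of a truncated master equation by linear algebra.

    The state space is every configuration with total copy number at most
    ``max_total`` over the N*K cells; transitions that would leave the
    truncation are dropped.  Intended as an oracle for toy systems only.
    """

    def __init__(self, model: ReactionDiffusionModel, max_total: int,
                 state_limit: int = 200_000):
        K, N = model.domain.K, model.n_species
        self.n = n = N * K
        self.model = model
        states = [np.array(s, dtype=np.int64) for s in
                  _compositions_upto(max_total, n)]
        if len(states) > state_limit:
            raise ValueError(f"state space too large: {len(states)} states")
        self.states = np.array(states)
        self._index = {tuple(s): i for i, s in enumerate(states)}

        rows, cols, vals = [], [], []
        diag = np.zeros(len(states))
        for si, z in enumerate(states):
            zmat = z.reshape(N, K)
            for r in model.reactions:
                for k in range(K):
                    counts = {nm: float(zmat[model.species_index(nm), k])
                              for nm in model.species_names}
                    lam = r.propensity(k + 1, counts, K)
                    if lam <= 0:
                        continue
                    tgt = zmat.copy()
                    for nm, dz in r.stoich.items():
                        tgt[model.species_index(nm), k] += dz
                    ti = self._index.get(tuple(tgt.reshape(-1)))
                    if ti is not None and np.all(tgt >= 0):
                        rows.append(ti); cols.append(si); vals.append(lam)
                        diag[si] += lam
            for i in range(N):
                q = model.jump_rate(i)
                for k in range(K):
                    if zmat[i, k] == 0 or q == 0:
                        continue
                    for dst in (k - 1, k + 1):
                        if not 0 <= dst < K:
                            continue
                        lam = q * zmat[i, k]
                        tgt = zmat.copy()
                        tgt[i, k] -= 1
                        tgt[i, dst] += 1
                        ti = self._index.get(tuple(tgt.reshape(-1)))
                        if ti is not None:
                            rows.append(ti); cols.append(si); vals.append(lam)
                            diag[si] += lam
        rows += list(range(len(states)))
        cols += list(range(len(states)))
        vals += list(-diag)
        self.Q = coo_matrix((vals, (rows, cols)),
                            shape=(len(states), len(states))).tocsc()

    def initial_distribution(self) -> np.ndarray:
        p0 = np.zeros(len(self.states))
        key = tuple(self.model.init.reshape(-1))
        if key not in self._index:
            raise ValueError("initial state outside the truncated state space")
        p0[self._index[key]] = 1.0
        return p0

    def transient(self, t: float, p0: np.ndarray | None = None) -> np.ndarray:
        p0 = self.initial_distribution() if p0 is None else p0
        if t == 0:
            return p0
        return np.maximum(expm_multiply(self.Q * t, p0), 0.0)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the class reachable from the initial state.

        Restricting to the forward-reachable states makes the problem well
        posed when a conservation law (e.g. pure diffusion) splits the
        truncated space into non-communicating blocks.
        """
        Qc = self.Q.tocsc()
        start = self._index[tuple(self.model.init.reshape(-1))]
        seen = {start}
        stack = [start]
        while stack:
            s = stack.pop()
            for t in Qc.indices[Qc.indptr[s]:Qc.indptr[s + 1]]:
                if t not in seen:
                    seen.add(int(t))
                    stack.append(int(t))
        idx = np.sort(np.fromiter(seen, dtype=np.int64))
        sub = self.Q.tocsr()[idx][:, idx].tolil()
        sub[0, :] = 1.0  # replace one balance equation by normalization
        rhs = np.zeros(len(idx))
        rhs[0] = 1.0
        psub = spsolve(sub.tocsc(), rhs)
        p = np.zeros(len(self.states))
        p[idx] = np.maximum(psub, 0.0)
        return p / p.sum()

    def moments(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) arrays of shape (N, K) under distribution ``p``."""
        K, N = self.model.domain.K, self.model.n_species
        mean = p @ self.states
        second = p @ self.states.astype(float) ** 2
        var = np.clip(second - mean ** 2, 0.0, None)
        return mean.reshape(N, K), np.sqrt(var).reshape(N, K)

    def marginal(self, cell: int, p: np.ndarray) -> np.ndarray:
        """Marginal pmf of flat cell ``cell`` under distribution ``p``."""
        top = int(self.states[:, cell].max())
        out = np.zeros(top + 1)
        np.add.at(out, self.states[:, cell], p)
        return out


def _compositions_upto(total: int, n: int):
    """All tuples of n non-negative ints summing to <= total."""
    if n == 1:
        for v in range(total + 1):
            yield (v,)
        return
    for v in range(total + 1):
        for rest in _compositions_upto(total - v, n - 1):
            yield (v,) + rest


def cme_enumerate(model: ReactionDiffusionModel, max_total: int) -> CMEDistribution:
    """Enumerate the truncated master equation of a tiny model."""
    return CMEDistribution(model, max_total)
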