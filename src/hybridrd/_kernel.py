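"""Compiled event loop shared by all solvers.

One numba kernel implements the coupled loop: Gillespie SSA events in the
Markov region (diffusive jumps, reactions, interface transfers) interleaved
with Euler–Maruyama updates of the SPDE region at fixed multiples of dt.
Waiting times use the total Markov-region propensity a0; the event selection
uniform r2 is drawn together with r1 and applied against the propensity table
frozen at draw time, as in the direct-method pseudocode.  Because interface
and reaction propensities depend on SPDE mesh values, the pending event time
is by default redrawn (memorylessly, from the refreshed a0) after every EM
update, which samples the piecewise-constant time-varying rates exactly; the
strictly frozen clock of the literal pseudocode is available as an option.

Randomness comes from two numpy SFC64 streams per realization, refilled in
blocks (batched generation is several times faster than per-draw generation
inside compiled code): a Gaussian stream consumed one row per EM step in a
fixed order (diffusion faces species-by-species left to right, then reaction
cells) and a uniform stream for event timing, selection and Scheme 1
placement draws.  Identical seeds therefore give bit-identical trajectories.
Runs that share a Gaussian block (common random numbers across interface
schemes in ensemble sweeps) remain individually deterministic because the
uniform streams are private.

The EM update is written inline in the main loop: for narrow SPDE regions
the per-step cost of a non-inlined many-argument helper call would dominate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import MARKOV, SPDE, HybridState

INF = 1e300
_EPS = 1e-9

_FIN = 0
_NEED_NOISE = 1
_NEED_UNIFORMS = 2
_DIVERGED = 3
_A0_MAX = 1e9   # total propensity beyond any physical rate: blown-up mesh
_U_MARGIN = 16          # max uniforms one loop iteration can consume
_U_BUF = 8192
_NOISE_BLOCK_VALUES = 1 << 16   # ~512 kB of float64 per noise block


@njit(cache=True)
def _recompute_mode(mode, region, r_order, r_involved):
    """mode[j,k]=1 (Langevin) iff order<=1 and every involved species is SPDE in k."""
    M, K = mode.shape
    N = region.shape[0]
    for j in range(M):
        for k in range(K):
            if r_order[j] >= 2:
                mode[j, k] = 0
                continue
            ok = True
            any_inv = False
            for i in range(N):
                if r_involved[j, i]:
                    any_inv = True
                    if region[i, k] != SPDE:
                        ok = False
            mode[j, k] = 1 if (ok and any_inv) else 0


@njit(cache=True, fastmath=True)
def _fill_propensities(prop, agg, comp, grid, region, mode,
                       r_order, r_s1, r_s2, r_rate,
                       jump_m, jump_s, scheme, psi1, psi2, edge_guard):
    """Propensity table: reactions (j,k), then left jumps (i,k), then right.

    Left/right jump entries cover plain Markov jumps, Markov->SPDE interface
    transfers (Scheme 2 scaled by psi1) and SPDE->Markov transfers (Scheme 1:
    pseudo-compartment total with the >=1 guard; Scheme 2: edge mesh cell
    scaled by psi2).  ``agg`` is an (N, K) scratch array for the
    compartment-aggregated copy numbers.
    """
    M, K = r_rate.shape
    N = comp.shape[0]
    A = grid.shape[2]
    for i in range(N):
        for k in range(K):
            if region[i, k] == MARKOV:
                agg[i, k] = comp[i, k]
            else:
                tot = 0.0
                for l in range(A):
                    tot += grid[i, k, l]
                agg[i, k] = tot
    a0 = 0.0
    for j in range(M):
        base = j * K
        for k in range(K):
            lam = 0.0
            if mode[j, k] == 0 and r_rate[j, k] > 0.0:
                lam = r_rate[j, k]
                if r_order[j] >= 1:
                    lam *= agg[r_s1[j], k]
                if r_order[j] == 2:
                    lam *= agg[r_s2[j], k]
                if lam < 0.0:
                    lam = 0.0
            prop[base + k] = lam
            a0 += lam
    for direction in range(2):  # 0: left jumps, 1: right jumps
        off = M * K + direction * N * K
        step = -1 if direction == 0 else 1
        for i in range(N):
            for k in range(K):
                lam = 0.0
                k2 = k + step
                if 0 <= k2 < K:
                    if region[i, k] == MARKOV:
                        lam = jump_m[i] * comp[i, k]
                        if region[i, k2] == SPDE and scheme == 2:
                            lam *= psi1
                    else:
                        if region[i, k2] == MARKOV:
                            if scheme == 1:
                                tot = agg[i, k]
                                lam = jump_m[i] * tot if tot >= 1.0 else 0.0
                            else:
                                edge = 0 if step == -1 else A - 1
                                x = grid[i, k, edge]
                                lam = (psi2 * jump_s[i] * x
                                       if x >= edge_guard else 0.0)
                prop[off + i * K + k] = lam
                a0 += lam
    return a0


@njit(cache=True, fastmath=True)
def _draw_next(t, prop, frozen_cum, agg, comp, grid, region, mode,
               r_order, r_s1, r_s2, r_rate, jump_m, jump_s,
               scheme, psi1, psi2, edge_guard, u_buf, upos):
    a0 = _fill_propensities(prop, agg, comp, grid, region, mode,
                            r_order, r_s1, r_s2, r_rate,
                            jump_m, jump_s, scheme, psi1, psi2, edge_guard)
    c = 0.0
    for e in range(prop.shape[0]):
        c += prop[e]
        frozen_cum[e] = c
    r1 = u_buf[upos]
    r2 = u_buf[upos + 1]
    upos += 2
    if a0 > 0.0 and r1 > 0.0:
        t_m = t - np.log(r1) / a0
    else:
        t_m = INF
    return t_m, r2, a0, upos


@njit(cache=True, fastmath=True)
def _apply_event(idx, comp, grid, region, r_stoich, scheme, transfer,
                 u_buf, upos):
    """Apply the selected event; returns the uniform-stream position."""
    M = r_stoich.shape[0]
    N, K, A = grid.shape
    if idx < M * K:
        j = idx // K
        k = idx % K
        for i in range(N):
            z = r_stoich[j, i]
            if z != 0:
                if region[i, k] == MARKOV:
                    comp[i, k] += z
                else:
                    frac = z / A
                    for l in range(A):
                        grid[i, k, l] += frac
        return upos
    rem = idx - M * K
    direction = 0 if rem < N * K else 1
    step = -1 if direction == 0 else 1
    rem2 = rem - direction * N * K
    i = rem2 // K
    k = rem2 % K
    k2 = k + step
    if region[i, k] == MARKOV:
        if comp[i, k] < 0.5:  # guard: jump fired from an empty compartment
            return upos
        comp[i, k] -= 1.0
        if region[i, k2] == MARKOV:
            comp[i, k2] += 1.0
        else:  # Markov -> SPDE transfer
            if scheme == 2:
                l = A - 1 if step == -1 else 0
                grid[i, k2, l] += 1.0
            elif transfer == 0:  # point: uniformly chosen mesh cell
                l = int(u_buf[upos] * A)
                upos += 1
                if l >= A:
                    l = A - 1
                grid[i, k2, l] += 1.0
            else:  # distributed
                frac = 1.0 / A
                for l in range(A):
                    grid[i, k2, l] += frac
    else:  # SPDE -> Markov transfer
        comp[i, k2] += 1.0
        if scheme == 2:
            l = 0 if step == -1 else A - 1
            grid[i, k, l] -= 1.0
        elif transfer == 0:
            l = int(u_buf[upos] * A)
            upos += 1
            if l >= A:
                l = A - 1
            grid[i, k, l] -= 1.0
        else:
            frac = 1.0 / A
            for l in range(A):
                grid[i, k, l] -= frac
    return upos


@njit(cache=True)
def _build_segments(region, A, seg_lo, seg_hi):
    """Contiguous SPDE mesh ranges per species, as flat-cell index ranges.

    Flat cell c of species i lives in grid.reshape(N, K*A); compartment k
    occupies cells [k*A, (k+1)*A), so adjacent SPDE compartments form one
    contiguous mesh segment.  Returns the per-species segment counts.
    """
    N, K = region.shape
    n_seg = np.zeros(N, dtype=np.int64)
    for i in range(N):
        open_run = False
        for k in range(K):
            if region[i, k] == SPDE:
                if not open_run:
                    seg_lo[i, n_seg[i]] = k * A
                    open_run = True
                seg_hi[i, n_seg[i]] = (k + 1) * A - 1
            else:
                if open_run:
                    n_seg[i] += 1
                    open_run = False
        if open_run:
            n_seg[i] += 1
    return n_seg


@njit(cache=True)
def _build_langevin(mode, r_order, r_s1, r_rate, cell_rate0,
                    lr_cell, lr_rate, lr_kind, lr_s1, lr_j):
    """Flat list of Langevin reaction cells, ordered by (j, k, l)."""
    M, K = mode.shape
    A = cell_rate0.shape[2]
    n = 0
    for j in range(M):
        for k in range(K):
            if mode[j, k] == 1:
                if r_order[j] == 0:
                    for l in range(A):
                        rate = cell_rate0[j, k, l]
                        if rate > 0.0:
                            lr_cell[n] = k * A + l
                            lr_rate[n] = rate
                            lr_kind[n] = 0
                            lr_s1[n] = -1
                            lr_j[n] = j
                            n += 1
                elif r_rate[j, k] > 0.0:
                    for l in range(A):
                        lr_cell[n] = k * A + l
                        lr_rate[n] = r_rate[j, k]
                        lr_kind[n] = 1
                        lr_s1[n] = r_s1[j]
                        lr_j[n] = j
                        n += 1
    return n


@njit(cache=True)
def _leading_spde(region):
    K = region.shape[1]
    ks = 0
    while ks < K and region[0, ks] == SPDE:
        ks += 1
    return ks


@njit(cache=True, fastmath=True)
def _check_and_move(comp, grid, region, q_lower, q_upper, diag):
    """Adaptive interface update: at most one move of +-h per check.

    SPDE->Markov conversion rounds the summed mesh mass to the nearest
    integer (clamped at 0); Markov->SPDE redistributes the count uniformly
    over the alpha mesh cells.  The interface stays within [0, L-h].
    """
    K = region.shape[1]
    A = grid.shape[2]
    ks = _leading_spde(region)
    if ks > 0:
        tot = 0.0
        for l in range(A):
            tot += grid[0, ks - 1, l]
        if tot < q_lower:
            r = np.rint(tot)
            if r < 0.0:
                r = 0.0
            comp[0, ks - 1] = r
            for l in range(A):
                grid[0, ks - 1, l] = 0.0
            region[0, ks - 1] = MARKOV
            diag[0] += 1.0
            diag[2] += r - tot
            return True
        if ks < K and comp[0, ks] > q_upper:
            if ks >= K - 1:  # interface may not move right of L-h
                diag[3] += 1.0
                return False
            c = comp[0, ks]
            frac = c / A
            for l in range(A):
                grid[0, ks, l] = frac
            comp[0, ks] = 0.0
            region[0, ks] = SPDE
            diag[1] += 1.0
            return True
        return False
    if comp[0, 0] > q_upper and K >= 2:
        c = comp[0, 0]
        frac = c / A
        for l in range(A):
            grid[0, 0, l] = frac
        comp[0, 0] = 0.0
        region[0, 0] = SPDE
        diag[1] += 1.0
        return True
    return False


@njit(cache=True, fastmath=True)
def _run_block(comp, grid, region, mode,
               jump_m, jump_s, cd, cn,
               r_order, r_s1, r_s2, r_rate, r_stoich, r_involved, cell_rate0,
               n_seg, seg_lo, seg_hi,
               lr_cell, lr_rate, lr_kind, lr_s1, lr_j, lr_scratch,
               st_ptr, st_i, st_z,
               scheme, transfer, psi1, psi2, edge_guard,
               noise_on, redraw_after_spde,
               dt, n_steps, record_times,
               adaptive_on, q_lower, q_upper, n_c,
               noise, m0, u_buf,
               prop, frozen_cum, agg, fctl, ictl,
               out_comp, out_ks, out_region, out_compraw, out_grid,
               record_cells, diag):
    # fctl: [t, t_m, r2, a0_frozen]
    # ictl: [m, rec_idx, initialized, nc_count, lr_count, u_pos]
    # diag: [n_conv_s2m, n_conv_m2s, rounding_defect, n_clamped, first_step_draws]
    N, K, A = grid.shape
    gflat = grid.reshape(N, K * A)
    n_rec = record_times.shape[0]
    n_events = prop.shape[0]
    t = fctl[0]
    t_m = fctl[1]
    r2 = fctl[2]
    a0f = fctl[3]
    m = ictl[0]
    rec_idx = ictl[1]
    nc_count = ictl[3]
    lr_count = ictl[4]
    upos = ictl[5]
    u_len = u_buf.shape[0]
    m_max = m0 + noise.shape[0]

    status = _FIN
    if ictl[2] == 0:
        t_m, r2, a0f, upos = _draw_next(t, prop, frozen_cum, agg, comp, grid,
                                        region, mode, r_order, r_s1, r_s2,
                                        r_rate, jump_m, jump_s, scheme,
                                        psi1, psi2, edge_guard, u_buf, upos)
        ictl[2] = 1


    while rec_idx < n_rec:
        if not (a0f <= _A0_MAX):   # also catches NaN
            status = _DIVERGED
            break
        if upos > u_len - _U_MARGIN:
            status = _NEED_UNIFORMS
            break
        if record_times[rec_idx] <= t + _EPS:
            for i in range(N):
                for k in range(K):
                    if region[i, k] == MARKOV:
                        out_comp[rec_idx, i, k] = comp[i, k]
                    else:
                        tot = 0.0
                        for l in range(A):
                            tot += grid[i, k, l]
                        out_comp[rec_idx, i, k] = tot
            out_ks[rec_idx] = _leading_spde(region)
            if record_cells:
                out_region[rec_idx] = region
                out_compraw[rec_idx] = comp
                out_grid[rec_idx] = grid
            rec_idx += 1
            continue
        t_s = (m + 1) * dt if m < n_steps else INF
        if t_m <= t_s:
            if record_times[rec_idx] <= t_m:
                t = record_times[rec_idx]
                continue
            t = t_m
            v = r2 * a0f
            idx = np.searchsorted(frozen_cum, v)
            if idx >= n_events:
                idx = n_events - 1
            upos = _apply_event(idx, comp, grid, region, r_stoich,
                                scheme, transfer, u_buf, upos)
            t_m, r2, a0f, upos = _draw_next(t, prop, frozen_cum, agg, comp,
                                            grid, region, mode, r_order, r_s1,
                                            r_s2, r_rate, jump_m, jump_s,
                                            scheme, psi1, psi2, edge_guard,
                                            u_buf, upos)
        else:
            if record_times[rec_idx] < t_s - _EPS:
                t = record_times[rec_idx]
                continue
            if m >= m_max:
                status = _NEED_NOISE
                break
            # ---- Euler–Maruyama step (inlined; see module docstring) ----
            # Reaction propensities are read off the pre-step state first;
            # the diffusion sweep then only needs the running `prev` value,
            # so no state copy is made.
            row = noise[m - m0]
            for e in range(lr_count):
                if lr_kind[e] == 0:
                    lr_scratch[e] = lr_rate[e]
                else:
                    lr_scratch[e] = lr_rate[e] * gflat[lr_s1[e], lr_cell[e]]
            cursor = 0
            for i in range(N):
                cdi = cd[i]
                cni = cn[i]
                for s in range(n_seg[i]):
                    lo = seg_lo[i, s]
                    hi = seg_hi[i, s]
                    prev = gflat[i, lo]
                    if noise_on:
                        for c in range(lo + 1, hi + 1):
                            cur = gflat[i, c]
                            F = cdi * (cur - prev)
                            sm = cur + prev
                            if sm >= 0.0:
                                F += np.sqrt(cni * sm) * row[cursor]
                            cursor += 1
                            gflat[i, c - 1] += F
                            gflat[i, c] -= F
                            prev = cur
                    else:
                        for c in range(lo + 1, hi + 1):
                            cur = gflat[i, c]
                            F = cdi * (cur - prev)
                            gflat[i, c - 1] += F
                            gflat[i, c] -= F
                            prev = cur
            for e in range(lr_count):
                rate = lr_scratch[e]
                d = rate * dt
                if noise_on:
                    amp = rate if rate > 0.0 else 0.0
                    d += np.sqrt(amp * dt) * row[cursor]
                    cursor += 1
                c = lr_cell[e]
                j = lr_j[e]
                for p in range(st_ptr[j], st_ptr[j + 1]):
                    gflat[st_i[p], c] += st_z[p] * d
            if m == 0:
                diag[4] = cursor
            m += 1
            t = m * dt
            moved = False
            if adaptive_on:
                nc_count += 1
                if nc_count >= n_c:
                    nc_count = 0
                    moved = _check_and_move(comp, grid, region,
                                            q_lower, q_upper, diag)
                    if moved:
                        _recompute_mode(mode, region, r_order, r_involved)
                        tmp = _build_segments(region, A, seg_lo, seg_hi)
                        for i in range(N):
                            n_seg[i] = tmp[i]
                        lr_count = _build_langevin(mode, r_order, r_s1,
                                                   r_rate, cell_rate0,
                                                   lr_cell, lr_rate, lr_kind,
                                                   lr_s1, lr_j)
            if moved or redraw_after_spde:
                t_m, r2, a0f, upos = _draw_next(t, prop, frozen_cum, agg,
                                                comp, grid, region, mode,
                                                r_order, r_s1, r_s2, r_rate,
                                                jump_m, jump_s, scheme,
                                                psi1, psi2, edge_guard,
                                                u_buf, upos)
    fctl[0] = t
    fctl[1] = t_m
    fctl[2] = r2
    fctl[3] = a0f
    ictl[0] = m
    ictl[1] = rec_idx
    ictl[3] = nc_count
    ictl[4] = lr_count
    ictl[5] = upos
    return status


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------


def _count_steps(t_end: float, dt: float) -> int:
    r = t_end / dt
    n = int(round(r))
    if abs(r - n) > 1e-9:
        n = int(np.floor(r))
    return n


class _RunState:
    """Per-realization mutable kernel state plus its private RNG streams."""

    def __init__(self, sim: "CompiledSim", ssa_seed: int, noise_seed: int,
                 record_cells: bool):
        st = sim.state0
        self.comp = st.comp.copy()
        self.grid = st.grid.copy()
        self.region = sim.region0.copy()
        self.mode = sim.mode0.copy()
        N, K, A = self.grid.shape
        n_rec = len(sim.record_times)
        self.record_cells = record_cells
        self.out_comp = np.zeros((n_rec, N, K))
        self.out_ks = np.zeros(n_rec, dtype=np.int64)
        if record_cells:
            self.out_region = np.zeros((n_rec, N, K), dtype=np.int8)
            self.out_compraw = np.zeros((n_rec, N, K))
            self.out_grid = np.zeros((n_rec, N, K, A))
        else:
            self.out_region = np.zeros((1, 1, 1), dtype=np.int8)
            self.out_compraw = np.zeros((1, 1, 1))
            self.out_grid = np.zeros((1, 1, 1, 1))
        self.seg_lo = np.zeros((N, K), dtype=np.int64)
        self.seg_hi = np.zeros((N, K), dtype=np.int64)
        self.n_seg = _build_segments(self.region, A, self.seg_lo, self.seg_hi)
        self.lr_cell = np.zeros(sim.lr_max, dtype=np.int64)
        self.lr_rate = np.zeros(sim.lr_max)
        self.lr_kind = np.zeros(sim.lr_max, dtype=np.int64)
        self.lr_s1 = np.zeros(sim.lr_max, dtype=np.int64)
        self.lr_j = np.zeros(sim.lr_max, dtype=np.int64)
        self.lr_scratch = np.zeros(sim.lr_max)
        self.prop = np.zeros(sim.n_events)
        self.frozen_cum = np.zeros(sim.n_events)
        self.agg = np.zeros((N, K))
        self.fctl = np.zeros(4)
        self.ictl = np.zeros(6, dtype=np.int64)
        self.ictl[4] = _build_langevin(self.mode, sim.r_order, sim.r_s1,
                                       sim.r_rate, sim.cell_rate0,
                                       self.lr_cell, self.lr_rate,
                                       self.lr_kind, self.lr_s1, self.lr_j)
        self.diag = np.zeros(5)
        self.u_gen = np.random.Generator(np.random.SFC64(ssa_seed))
        self.u_buf = np.empty(_U_BUF)
        self.u_gen.random(out=self.u_buf)
        self.noise_gen = np.random.Generator(np.random.SFC64(noise_seed))
        self.done = False

    def refill_uniforms(self) -> None:
        self.u_gen.random(out=self.u_buf)
        self.ictl[5] = 0

    def output(self, sim: "CompiledSim") -> dict:
        return {
            "times": sim.record_times,
            "comp": self.out_comp,
            "ks": self.out_ks,
            "region": self.out_region if self.record_cells else None,
            "compraw": self.out_compraw if self.record_cells else None,
            "grid": self.out_grid if self.record_cells else None,
            "diag": self.diag,
        }


class CompiledSim:
    """A model + partition + scheme compiled to plain arrays for the kernel.

    Build once, then :meth:`run` per realization.  The compiled object is
    reusable and stateless across runs (each run copies the initial state).
    """

    def __init__(self, model, state0: HybridState,
                 scheme: str = "scheme1", transfer_mode: str = "point",
                 psi1: float | None = None, psi2: float | None = None,
                 edge_guard: float = 0.0,
                 noise_on: bool = True, redraw_after_spde: bool = True,
                 dt: float = 5e-4, t_end: float = 1.0,
                 record_times=None, adaptive=None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        dom = model.domain
        K, N = dom.K, model.n_species
        A = state0.alpha
        self.model = model
        self.alpha = A
        self.dx = dom.h / A
        self.dt = float(dt)
        self.t_end = float(t_end)
        self.scheme = {"scheme1": 1, "scheme2": 2}[scheme]
        self.transfer = {"point": 0, "distributed": 1}[transfer_mode]
        self.psi1 = float(psi1) if psi1 is not None else 2 * dom.h / (self.dx + dom.h)
        self.psi2 = float(psi2) if psi2 is not None else 2 * self.dx / (self.dx + dom.h)
        self.edge_guard = float(edge_guard)
        self.noise_on = bool(noise_on)
        self.redraw_after_spde = bool(redraw_after_spde)

        rec = np.atleast_1d(np.asarray(
            [t_end] if record_times is None else record_times, dtype=np.float64))
        if np.any(np.diff(rec) < 0):
            raise ValueError("record_times must be non-decreasing")
        if rec[-1] > t_end + _EPS:
            raise ValueError("record_times beyond t_end")
        self.record_times = rec

        self.state0 = state0.copy()
        self.region0 = state0.region.copy()

        # reactions -> arrays
        M = len(model.reactions)
        self.r_order = np.zeros(M, dtype=np.int64)
        self.r_s1 = np.full(M, -1, dtype=np.int64)
        self.r_s2 = np.full(M, -1, dtype=np.int64)
        self.r_rate = np.zeros((M, K))
        self.r_stoich = np.zeros((M, N), dtype=np.int64)
        self.r_involved = np.zeros((M, N), dtype=np.bool_)
        self.cell_rate0 = np.zeros((M, K, A))
        for j, r in enumerate(model.reactions):
            self.r_order[j] = r.order
            if r.order >= 1:
                self.r_s1[j] = model.species_index(r.reactants[0])
            if r.order == 2:
                self.r_s2[j] = model.species_index(r.reactants[1])
            for k in range(1, K + 1):
                self.r_rate[j, k - 1] = r.rate_in(k, K)
            for name, z in r.stoich.items():
                self.r_stoich[j, model.species_index(name)] = z
            for name in r.involved:
                self.r_involved[j, model.species_index(name)] = True
            if r.order == 0:
                if r.spde_placement == "first_cell":
                    self.cell_rate0[j, :, 0] = self.r_rate[j]
                else:
                    self.cell_rate0[j, :, :] = self.r_rate[j][:, None] / A

        self.jump_m = np.array([model.jump_rate(i) for i in range(N)])
        self.jump_s = np.array([s.D / self.dx ** 2 for s in model.species])
        self.cd = self.jump_s * self.dt
        self.cn = self.jump_s * self.dt

        self.mode0 = np.zeros((M, K), dtype=np.int8)
        _recompute_mode(self.mode0, self.region0, self.r_order, self.r_involved)

        # stoichiometry in compressed form: per reaction, (species, change)
        ptr = [0]
        st_i, st_z = [], []
        for j in range(M):
            for i in range(N):
                if self.r_stoich[j, i] != 0:
                    st_i.append(i)
                    st_z.append(float(self.r_stoich[j, i]))
            ptr.append(len(st_i))
        self.st_ptr = np.array(ptr, dtype=np.int64)
        self.st_i = np.array(st_i, dtype=np.int64) if st_i else np.zeros(0, np.int64)
        self.st_z = np.array(st_z) if st_z else np.zeros(0)
        self.lr_max = max(M * K * A, 1)

        self.adaptive = adaptive
        self.adaptive_on = adaptive is not None
        if self.adaptive_on and N != 1:
            raise ValueError("the adaptive interface supports single-species models")
        if self.adaptive_on:
            self.q_lower = float(adaptive.q_lower)
            self.q_upper = float(adaptive.q_upper)
            self.n_c = int(adaptive.n_c)
        else:
            self.q_lower = self.q_upper = 0.0
            self.n_c = 1

        any_spde = bool(np.any(self.region0 == SPDE))
        if any_spde or adaptive is not None:
            courant = float(np.max(self.jump_s) * self.dt)
            if courant > 0.5:
                import warnings
                warnings.warn(
                    f"D*dt/dx^2 = {courant:.3g} exceeds the stability bound "
                    "1/2 of the explicit Euler-Maruyama step; the mesh "
                    "dynamics will be unstable", RuntimeWarning, stacklevel=3)
        self.n_steps = _count_steps(t_end, dt) if (any_spde or self.adaptive_on) else 0
        self.n_events = (M + 2 * N) * K
        self.width = self._noise_width(self.region0, self.mode0)
        if self.adaptive_on:
            full = np.full_like(self.region0, SPDE)
            fmode = np.zeros((M, K), dtype=np.int8)
            _recompute_mode(fmode, full, self.r_order, self.r_involved)
            self.width = max(self.width, self._noise_width(full, fmode))

    def _noise_width(self, region, mode) -> int:
        """Gaussian draws consumed per EM step (must match the kernel exactly)."""
        if not self.noise_on:
            return 0
        N, K = region.shape
        A = self.alpha
        w = 0
        for i in range(N):
            run = 0
            for k in range(K):
                if region[i, k] == SPDE:
                    run += A
                else:
                    if run > 0:
                        w += run - 1
                    run = 0
            if run > 0:
                w += run - 1
        for j in range(self.r_order.shape[0]):
            for k in range(K):
                if mode[j, k] == 1:
                    if self.r_order[j] == 0:
                        w += int(np.count_nonzero(self.cell_rate0[j, k] > 0))
                    elif self.r_rate[j, k] > 0:
                        w += A
        return w

    def _block_call(self, S: _RunState, noise: np.ndarray, m0: int) -> int:
        return _run_block(
            S.comp, S.grid, S.region, S.mode,
            self.jump_m, self.jump_s, self.cd, self.cn,
            self.r_order, self.r_s1, self.r_s2, self.r_rate,
            self.r_stoich, self.r_involved, self.cell_rate0,
            S.n_seg, S.seg_lo, S.seg_hi,
            S.lr_cell, S.lr_rate, S.lr_kind, S.lr_s1, S.lr_j, S.lr_scratch,
            self.st_ptr, self.st_i, self.st_z,
            self.scheme, self.transfer, self.psi1, self.psi2,
            self.edge_guard, self.noise_on, self.redraw_after_spde,
            self.dt, self.n_steps, self.record_times,
            self.adaptive_on, self.q_lower, self.q_upper, self.n_c,
            noise, m0, S.u_buf,
            S.prop, S.frozen_cum, S.agg, S.fctl, S.ictl,
            S.out_comp, S.out_ks, S.out_region, S.out_compraw, S.out_grid,
            S.record_cells, S.diag)

    def _finish_block(self, S: _RunState, noise: np.ndarray, m0: int) -> None:
        """Advance one run until it exhausts this noise block (or finishes)."""
        while True:
            status = self._block_call(S, noise, m0)
            if status == _NEED_UNIFORMS:
                S.refill_uniforms()
                continue
            if status == _DIVERGED:
                raise RuntimeError(
                    "total propensity diverged: the SPDE mesh has blown up. "
                    "The explicit Euler-Maruyama step requires "
                    "D*dt/dx^2 <= 1/2; reduce dt or coarsen the mesh.")
            if status == _FIN:
                S.done = True
            return

    def _check_accounting(self, S: _RunState) -> None:
        if self.width > 0 and self.n_steps > 0 and not self.adaptive_on:
            assert int(S.diag[4]) == self.width, \
                f"noise accounting mismatch: {int(S.diag[4])} != {self.width}"

    def run(self, ssa_seed: int, noise_seed: int, record_cells: bool = False):
        """One realization; returns a dict of raw output arrays."""
        S = _RunState(self, ssa_seed, noise_seed, record_cells)
        width = max(self.width, 1)
        block_rows = max(1, _NOISE_BLOCK_VALUES // width)
        buf = np.empty((min(block_rows, max(self.n_steps, 1)), width))
        m0 = 0
        while not S.done:
            rows = max(min(self.n_steps - m0, buf.shape[0]), 1)
            noise = buf[:rows]
            if self.width > 0:
                S.noise_gen.standard_normal(out=noise)
            self._finish_block(S, noise, m0)
            m0 += rows
        self._check_accounting(S)
        return S.output(self)

    def debug_propensities(self, state: HybridState) -> tuple[np.ndarray, float]:
        """Kernel propensity table at a given state (for cross-checks)."""
        prop = np.zeros(self.n_events)
        mode = np.zeros_like(self.mode0)
        agg = np.zeros(state.comp.shape)
        _recompute_mode(mode, state.region, self.r_order, self.r_involved)
        a0 = _fill_propensities(prop, agg, state.comp, state.grid, state.region, mode,
                                self.r_order, self.r_s1, self.r_s2, self.r_rate,
                                self.jump_m, self.jump_s, self.scheme,
                                self.psi1, self.psi2, self.edge_guard)
        return prop, a0


def run_shared_noise(sims: list[CompiledSim], ssa_seed: int, noise_seed: int,
                     record_cells: bool = False) -> list[dict]:
    """Run one realization of several compiled sims on a shared Gaussian block.

    All sims must use the same per-step noise width and step count (e.g. the
    two interface schemes on the same model and mesh).  Each sim keeps its
    own uniform stream, so every run is individually reproducible; sharing
    the Gaussian stream implements common random numbers across the sims
    without changing any single ensemble's statistics.
    """
    base = sims[0]
    for s in sims[1:]:
        if s.width != base.width or s.n_steps != base.n_steps:
            raise ValueError("shared-noise runs require identical noise layout")
    states = [_RunState(s, ssa_seed, noise_seed, record_cells) for s in sims]
    width = max(base.width, 1)
    block_rows = max(1, _NOISE_BLOCK_VALUES // width)
    buf = np.empty((min(block_rows, max(base.n_steps, 1)), width))
    noise_gen = states[0].noise_gen
    m0 = 0
    while not all(S.done for S in states):
        rows = max(min(base.n_steps - m0, buf.shape[0]), 1)
        noise = buf[:rows]
        if base.width > 0:
            noise_gen.standard_normal(out=noise)
        for sim, S in zip(sims, states):
            if not S.done:
                sim._finish_block(S, noise, m0)
        m0 += rows
    out = []
    for sim, S in zip(sims, states):
        sim._check_accounting(S)
        out.append(S.output(sim))
    return out
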