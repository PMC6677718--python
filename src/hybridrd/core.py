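"""Domain geometry, species/reaction descriptions, partitions and hybrid state.

The simulator works on an elongated pseudo-one-dimensional domain
``[0, L] x [0, h_y] x [0, h_z]`` divided into ``K`` well-mixed compartments of
length ``h``.  A :class:`Partition` splits the compartments, per species, into
an SPDE region (each compartment further discretized into ``alpha`` mesh cells
of size ``dx = h / alpha``) and a Markov region (integer copy numbers,
simulated by the Gillespie SSA).  :class:`HybridState` carries the mixed
resolution state; :class:`CellIndexMap` is the single authority translating
1-based compartment coordinates to 0-based flat cell indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MARKOV = 0
SPDE = 1

_KIND_CODE = {"markov": MARKOV, "spde": SPDE}
_KIND_NAME = {MARKOV: "markov", SPDE: "spde"}


@dataclass(frozen=True)
class Domain:
    """Elongated cuboid domain of length ``L`` split into ``K`` compartments.

    All lengths are in micrometres; the compartment volume ``V_h = h*h_y*h_z``
    is in cubic micrometres.
    """

    L: float
    K: int
    h: float
    h_y: float = 1.0
    h_z: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1 or int(self.K) != self.K:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        for name in ("L", "h", "h_y", "h_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"domain length {name} must be positive")
        if abs(self.L - self.K * self.h) > 1e-12 * max(self.L, self.K * self.h):
            raise ValueError(
                f"inconsistent geometry: L={self.L} but K*h={self.K * self.h}"
            )

    @classmethod
    def from_compartments(cls, K: int, h: float, h_y: float = 1.0, h_z: float = 1.0) -> "Domain":
        return cls(L=K * h, K=K, h=h, h_y=h_y, h_z=h_z)

    @property
    def V_h(self) -> float:
        """Compartment volume h*h_y*h_z (µm³)."""
        return self.h * self.h_y * self.h_z


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species with diffusion constant ``D`` (µm²/s)."""

    name: str
    D: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"diffusion constant of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction with integer net stoichiometry and a mass-action propensity.

    ``order`` 0, 1 or 2; ``rate`` is the rate constant (per compartment, s⁻¹
    for order 0); ``profile`` optionally modulates the rate per compartment
    (e.g. a production term active in compartment 1 only, or a Gaussian
    spatial profile).  For zeroth-order reactions simulated inside the SPDE
    region, ``spde_placement`` selects whether the compartment rate is spread
    uniformly over the alpha mesh cells or concentrated in the cell nearest
    the left domain boundary (a flux-type source).
    """

    name: str
    order: int
    stoich: Mapping[str, int]
    reactants: tuple[str, ...] = ()
    rate: float = 0.0
    profile: tuple[float, ...] | None = None
    spde_placement: str = "uniform"

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"reaction order must be 0, 1 or 2, got {self.order}")
        if len(self.reactants) != self.order:
            raise ValueError(
                f"reaction {self.name!r}: order {self.order} needs "
                f"{self.order} reactants, got {self.reactants}"
            )
        if self.rate < 0:
            raise ValueError(f"reaction {self.name!r}: negative rate constant")
        if self.spde_placement not in ("uniform", "first_cell"):
            raise ValueError(f"unknown spde_placement {self.spde_placement!r}")

    # -- constructors --------------------------------------------------
    @staticmethod
    def zeroth(name: str, stoich: Mapping[str, int], rate: float,
               profile: Sequence[float] | None = None,
               spde_placement: str = "uniform") -> "ReactionSpec":
        return ReactionSpec(name, 0, dict(stoich), (), rate,
                            None if profile is None else
                            tuple(float(x) for x in profile), spde_placement)

    @staticmethod
    def first(name: str, reactant: str, stoich: Mapping[str, int], rate: float,
              profile: Sequence[float] | None = None) -> "ReactionSpec":
        return ReactionSpec(name, 1, dict(stoich), (reactant,), rate,
                            None if profile is None else
                            tuple(float(x) for x in profile))

    @staticmethod
    def second(name: str, reactants: Sequence[str], stoich: Mapping[str, int],
               rate: float, profile: Sequence[float] | None = None) -> "ReactionSpec":
        r = tuple(reactants)
        if len(r) != 2:
            raise ValueError("second-order reaction needs two reactants")
        return ReactionSpec(name, 2, dict(stoich), r, rate,
                            None if profile is None else
                            tuple(float(x) for x in profile))

    # -- evaluation ----------------------------------------------------
    def rate_in(self, k: int, K: int) -> float:
        """Rate constant in 1-based compartment ``k`` (profile applied)."""
        if self.profile is None:
            return self.rate
        if len(self.profile) != K:
            raise ValueError(
                f"reaction {self.name!r}: profile length {len(self.profile)} != K={K}"
            )
        return self.rate * self.profile[k - 1]

    def propensity(self, k: int, counts: Mapping[str, float], K: int) -> float:
        """Propensity lambda_j^k for per-compartment copy numbers ``counts``."""
        lam = self.rate_in(k, K)
        for r in self.reactants:
            lam *= counts[r]
        return max(lam, 0.0)

    @property
    def involved(self) -> frozenset[str]:
        """Species whose representation matters for this reaction."""
        return frozenset(self.reactants) | frozenset(
            s for s, z in self.stoich.items() if z != 0
        )


class ReactionDiffusionModel:
    """A validated, immutable compartment-based reaction–diffusion model.

    Diffusion is a jump process between neighbouring compartments with
    per-molecule rate ``D_i / h²``.
    """

    def __init__(self, domain: Domain, species: Sequence[SpeciesSpec],
                 reactions: Sequence[ReactionSpec],
                 init: Mapping[str, Sequence[int]] | np.ndarray):
        self.domain = domain
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self._index = {n: i for i, n in enumerate(names)}

        K, N = domain.K, len(self.species)
        if isinstance(init, Mapping):
            arr = np.zeros((N, K), dtype=np.int64)
            for name, counts in init.items():
                arr[self.species_index(name)] = np.asarray(counts)
        else:
            arr = np.asarray(init, dtype=np.int64)
        if arr.shape != (N, K):
            raise ValueError(f"init must have shape (N={N}, K={K}), got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("initial copy numbers must be non-negative")
        finit = np.asarray(init, dtype=float) if not isinstance(init, Mapping) else arr
        if not np.array_equal(np.asarray(finit, dtype=float), arr):
            raise ValueError("initial copy numbers must be integers")
        self.init = arr
        self.init.setflags(write=False)

        for r in self.reactions:
            for s in r.involved:
                if s not in self._index:
                    raise ValueError(f"reaction {r.name!r} references unknown species {s!r}")
            if r.profile is not None and len(r.profile) != K:
                raise ValueError(f"reaction {r.name!r}: profile length must equal K={K}")

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        return self._index[name]

    def jump_rate(self, i: int) -> float:
        """Per-molecule diffusion jump rate D_i/h² of species ``i``."""
        return self.species[i].D / self.domain.h ** 2

    def __repr__(self) -> str:
        return (f"ReactionDiffusionModel(K={self.domain.K}, "
                f"species={list(self.species_names)}, "
                f"reactions={[r.name for r in self.reactions]})")


def build_model(domain: Domain, species: Sequence[SpeciesSpec],
                reactions: Sequence[ReactionSpec],
                init: Mapping[str, Sequence[int]] | np.ndarray) -> ReactionDiffusionModel:
    """Build and validate a compartment-based reaction–diffusion model."""
    return ReactionDiffusionModel(domain, species, reactions, init)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

Block = tuple[str, int, int]  # (kind, first compartment, last compartment), 1-based


def _validate_blocks(blocks: Sequence[Block], K: int) -> tuple[Block, ...]:
    out = []
    expect = 1
    for kind, lo, hi in blocks:
        if kind not in _KIND_CODE:
            raise ValueError(f"unknown region kind {kind!r}")
        if lo != expect:
            raise ValueError(f"blocks must tile 1..{K} without gaps/overlaps "
                             f"(expected block starting at {expect}, got {lo})")
        if hi < lo:
            raise ValueError(f"empty block ({kind}, {lo}, {hi})")
        out.append((kind, int(lo), int(hi)))
        expect = hi + 1
    if expect != K + 1:
        raise ValueError(f"blocks cover 1..{expect - 1}, domain has K={K}")
    return tuple(out)


@dataclass(frozen=True)
class Partition:
    """Split of the K compartments into SPDE and Markov regions.

    ``blocks`` is the default split; ``per_species`` overrides it for named
    species (different species may use different splits).  ``alpha`` is the
    number of SPDE mesh cells per compartment, so the SPDE mesh size is
    ``dx = h / alpha`` exactly.
    """

    blocks: tuple[Block, ...]
    alpha: int
    per_species: Mapping[str, tuple[Block, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha < 1 or int(self.alpha) != self.alpha:
            raise ValueError(f"alpha must be a positive integer, got {self.alpha}")

    @staticmethod
    def all_markov(K: int, alpha: int = 1) -> "Partition":
        return Partition((("markov", 1, K),), alpha)

    @staticmethod
    def all_spde(K: int, alpha: int) -> "Partition":
        return Partition((("spde", 1, K),), alpha)

    @staticmethod
    def split(K_s: int, K: int, alpha: int) -> "Partition":
        """SPDE on compartments 1..K_s, Markov on K_s+1..K (interface I=K_s·h)."""
        if K_s == 0:
            return Partition.all_markov(K, alpha)
        if K_s == K:
            return Partition.all_spde(K, alpha)
        return Partition((("spde", 1, K_s), ("markov", K_s + 1, K)), alpha)

    def blocks_for(self, species: str | None) -> tuple[Block, ...]:
        if species is not None and species in self.per_species:
            return tuple(self.per_species[species])
        return self.blocks

    def region_array(self, K: int, species: str | None = None) -> np.ndarray:
        """int8 array of length K with 0=markov, 1=spde per compartment."""
        arr = np.empty(K, dtype=np.int8)
        for kind, lo, hi in _validate_blocks(self.blocks_for(species), K):
            arr[lo - 1:hi] = _KIND_CODE[kind]
        return arr

    def dx(self, h: float) -> float:
        return h / self.alpha


@dataclass(frozen=True)
class Interface:
    """Boundary between adjacent compartments of different kind.

    ``pseudo_compartment`` is the SPDE-side compartment (Scheme 1's virtual
    compartment), ``boundary_compartment`` the Markov-side one; both 1-based.
    """

    left: int           # compartment index left of the interface
    right: int          # = left + 1
    spde_side: str      # 'left' or 'right'

    @property
    def pseudo_compartment(self) -> int:
        return self.left if self.spde_side == "left" else self.right

    @property
    def boundary_compartment(self) -> int:
        return self.right if self.spde_side == "left" else self.left


class CellIndexMap:
    """Bidirectional map between (compartment k, grid offset ℓ) and flat index.

    Compartments are 1-based (k=1..K) and grid offsets 1-based (ℓ=1..alpha)
    to match the usual mathematical indexing; flat indices are 0-based.
    """

    def __init__(self, kinds: np.ndarray, alpha: int):
        self.kinds = np.asarray(kinds, dtype=np.int8)
        self.alpha = int(alpha)
        K = len(self.kinds)
        sizes = np.where(self.kinds == SPDE, self.alpha, 1)
        self.offsets = np.concatenate(([0], np.cumsum(sizes)))  # length K+1
        self.flat_len = int(self.offsets[-1])
        self.K = K

    def kind(self, k: int) -> str:
        return _KIND_NAME[int(self.kinds[k - 1])]

    def to_flat(self, k: int, ell: int | None = None) -> int:
        if not 1 <= k <= self.K:
            raise IndexError(f"compartment {k} outside 1..{self.K}")
        if self.kinds[k - 1] == SPDE:
            if ell is None:
                raise ValueError(f"compartment {k} is SPDE; a grid offset is required")
            if not 1 <= ell <= self.alpha:
                raise IndexError(f"grid offset {ell} outside 1..{self.alpha}")
            return int(self.offsets[k - 1]) + ell - 1
        if ell not in (None, 1):
            raise ValueError(f"compartment {k} is Markov; it has no grid offsets")
        return int(self.offsets[k - 1])

    def from_flat(self, idx: int) -> tuple[int, int | None]:
        if not 0 <= idx < self.flat_len:
            raise IndexError(f"flat index {idx} outside 0..{self.flat_len - 1}")
        k = int(np.searchsorted(self.offsets, idx, side="right"))
        off = idx - int(self.offsets[k - 1])
        return (k, off + 1) if self.kinds[k - 1] == SPDE else (k, None)

    @property
    def interfaces(self) -> tuple[Interface, ...]:
        out = []
        for k in range(1, self.K):
            a, b = self.kinds[k - 1], self.kinds[k]
            if a != b:
                out.append(Interface(k, k + 1, "left" if a == SPDE else "right"))
        return tuple(out)

    def pseudo_cells(self, iface: Interface) -> list[int]:
        """Flat indices of the alpha grid points of the pseudo-compartment."""
        k = iface.pseudo_compartment
        return [self.to_flat(k, ell) for ell in range(1, self.alpha + 1)]


def layout(partition: Partition, domain: Domain, species: str | None = None) -> CellIndexMap:
    """Build the flat cell layout for one species' partition of ``domain``."""
    return CellIndexMap(partition.region_array(domain.K, species), partition.alpha)


# ---------------------------------------------------------------------------
# Hybrid state
# ---------------------------------------------------------------------------

class HybridState:
    """Mixed-resolution state: real-valued SPDE mesh cells, integer Markov cells.

    Internally the state is stored per species as a per-compartment pair
    ``comp[i, k]`` (Markov copy number, used where ``region[i, k]`` is Markov)
    and ``grid[i, k, ℓ]`` (SPDE mesh values, used where it is SPDE).  SPDE
    values may transiently become negative; Markov values are integers >= 0 at
    all times.  ``flat(species)`` exposes the left-to-right flat layout.
    """

    def __init__(self, species_names: Sequence[str], region: np.ndarray,
                 alpha: int, comp: np.ndarray, grid: np.ndarray, t: float = 0.0):
        self.species_names = tuple(species_names)
        self.region = np.asarray(region, dtype=np.int8)
        self.alpha = int(alpha)
        self.comp = np.asarray(comp, dtype=np.float64)
        self.grid = np.asarray(grid, dtype=np.float64)
        self.t = float(t)
        N, K = self.region.shape
        if self.comp.shape != (N, K) or self.grid.shape != (N, K, self.alpha):
            raise ValueError("inconsistent state array shapes")

    @classmethod
    def from_compartment_counts(cls, model: ReactionDiffusionModel,
                                partition: Partition,
                                counts: np.ndarray | None = None,
                                t: float = 0.0) -> "HybridState":
        """Spread per-compartment counts over the partition (count/alpha per cell)."""
        K, N, A = model.domain.K, model.n_species, partition.alpha
        counts = model.init if counts is None else np.asarray(counts, dtype=float)
        region = np.stack([partition.region_array(K, n) for n in model.species_names])
        comp = np.zeros((N, K))
        grid = np.zeros((N, K, A))
        for i in range(N):
            for k in range(K):
                if region[i, k] == SPDE:
                    grid[i, k, :] = counts[i, k] / A
                else:
                    comp[i, k] = counts[i, k]
        return cls(model.species_names, region, A, comp, grid, t)

    def copy(self) -> "HybridState":
        return HybridState(self.species_names, self.region.copy(), self.alpha,
                           self.comp.copy(), self.grid.copy(), self.t)

    def _idx(self, species: int | str) -> int:
        if isinstance(species, str):
            return self.species_names.index(species)
        return species

    def per_compartment(self) -> np.ndarray:
        """(N, K) array of compartment-aggregated copy numbers."""
        spde = self.region == SPDE
        return np.where(spde, self.grid.sum(axis=2), self.comp)

    def total(self, species: int | str | None = None) -> float:
        agg = self.per_compartment()
        return float(agg.sum() if species is None else agg[self._idx(species)].sum())

    def index_map(self, species: int | str = 0) -> CellIndexMap:
        return CellIndexMap(self.region[self._idx(species)], self.alpha)

    def flat(self, species: int | str = 0) -> np.ndarray:
        """Flat left-to-right cell layout of one species (0-based)."""
        i = self._idx(species)
        parts = []
        for k in range(self.region.shape[1]):
            if self.region[i, k] == SPDE:
                parts.append(self.grid[i, k, :])
            else:
                parts.append(self.comp[i, k:k + 1])
        return np.concatenate(parts)

    def validate(self) -> None:
        """Check the Markov invariants: integer-valued, non-negative."""
        mk = self.region == MARKOV
        vals = self.comp[mk]
        if np.any(vals < 0):
            raise ValueError("negative Markov copy number")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("non-integer Markov copy number")


# ---------------------------------------------------------------------------
# Random number stream plumbing
# ---------------------------------------------------------------------------

class RNGStream:
    """Deterministic seed fan-out for ensembles.

    A single base seed spawns one child :class:`numpy.random.SeedSequence` per
    realization (counter-based, so ensembles are order-independent); each
    child yields one 31-bit seed for the SSA/event stream (Mersenne Twister
    uniforms, including interface placement draws) and one for the Gaussian
    increment stream (SFC64).  Identical seeds give bit-identical
    trajectories for a fixed model, scheme and time step.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._ss = np.random.SeedSequence(self.seed)

    def realization_seeds(self, n: int, start: int = 0) -> list[tuple[int, int]]:
        children = np.random.SeedSequence(self.seed).spawn(start + n)[start:]
        out = []
        for c in children:
            a, b = c.generate_state(2, dtype=np.uint32)
            out.append((int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF))
        return out

    def single(self) -> tuple[int, int]:
        return self.realization_seeds(1)[0]
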