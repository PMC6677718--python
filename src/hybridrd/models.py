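"""Packaged example models: morphogen gradient, two-compartment diffusion,
and the two-species pom1p gradient.

The morphogen model describes a single species produced at the left end of a
20 µm domain (a flux-type source of 25 molecules/s entering compartment 1 —
in the SPDE region, the first mesh interval), degraded everywhere at
0.05 s⁻¹ and diffusing at 0.8 µm²/s.  The two-compartment model strips this
down to pure diffusion of 50 molecules between one SPDE and one Markov
compartment, the minimal setting in which the interface schemes can be
compared against the exact Binomial(50, 1/2) stationary law.

The pom1p model follows the fission-yeast polarity gradient: slow-diffusing
clusters S1 and fast-diffusing particles S2, produced along a Gaussian
profile centred mid-domain, with cluster fragmentation S1 -> S2, aggregation
S1 + S2 -> 2 S1 and particle dissociation S2 -> 0.  S1 is abundant only in
the mid-domain and uses an SPDE description there (two static interfaces);
S2 is scarce and stays compartment-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (SPDE, Domain, HybridState, Partition, ReactionSpec,
                   ReactionDiffusionModel, SpeciesSpec, build_model)


# ---------------------------------------------------------------------------
# Morphogen gradient
# ---------------------------------------------------------------------------

#: Morphogen parameters: L, D (µm²/s), delta (1/s), J (1/(µm² s)), h, dt (s)
MORPHOGEN_PARAMS = dict(L=20.0, K=20, h=1.0, h_y=1.0, h_z=1.0,
                        D=0.8, delta=0.05, J=25.0, dx=0.2, dt=5e-4)


def morphogen_model(alpha: int = 5, J: float | None = None,
                    delta: float | None = None, initial: str = "left-half"):
    """Morphogen model and its default half-domain partition (I = L/2).

    The production flux density J (µm⁻² s⁻¹) enters through the h_y x h_z
    face, so the compartment propensity is J*h_y*h_z = 25 s⁻¹ in compartment
    1 only; in the SPDE region the whole rate is placed in the first mesh
    interval.  With ``initial="left-half"`` (the static-interface studies)
    500 molecules start uniformly in the left half, 50 per compartment in
    1..10; ``initial="empty"`` starts from zero copies (the moving-interface
    studies, where the gradient forms dynamically).
    """
    p = MORPHOGEN_PARAMS
    J = p["J"] if J is None else J
    delta = p["delta"] if delta is None else delta
    dom = Domain(L=p["L"], K=p["K"], h=p["h"], h_y=p["h_y"], h_z=p["h_z"])
    production = J * dom.h_y * dom.h_z
    reactions = []
    if production > 0:
        profile = np.zeros(dom.K)
        profile[0] = 1.0
        reactions.append(ReactionSpec.zeroth(
            "production", {"S": +1}, production, profile=profile,
            spde_placement="first_cell"))
    if delta > 0:
        reactions.append(ReactionSpec.first("degradation", "S", {"S": -1}, delta))
    init = np.zeros((1, dom.K), dtype=np.int64)
    if initial == "left-half":
        init[0, :10] = 50
    elif initial != "empty":
        raise ValueError(f"unknown initial condition {initial!r}")
    model = build_model(dom, [SpeciesSpec("S", p["D"])], reactions, init)
    partition = Partition.split(K_s=10, K=dom.K, alpha=alpha)
    return model, partition


# ---------------------------------------------------------------------------
# Two-compartment diffusion
# ---------------------------------------------------------------------------

def two_compartment_model(alpha: int = 10):
    """Pure diffusion of 50 molecules between an SPDE and a Markov compartment.

    K=2, h=1 µm, D=0.8 µm²/s, no reactions; all 50 molecules start in the
    SPDE compartment (spread 50/alpha per mesh cell in hybrid runs).  The
    hybrid state vector has alpha + 1 cells.
    """
    dom = Domain.from_compartments(K=2, h=1.0)
    init = np.array([[50, 0]], dtype=np.int64)
    model = build_model(dom, [SpeciesSpec("S", 0.8)], [], init)
    partition = Partition.split(K_s=1, K=2, alpha=alpha)
    return model, partition


# ---------------------------------------------------------------------------
# pom1p gradient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pom1pParams:
    """Rate constants and geometry of the two-state pom1p gradient model."""

    L: float = 14.0          # µm
    K: int = 40
    h: float = 0.35          # µm
    I1: float = 3.5          # µm, left boundary of the S1 SPDE region
    I2: float = 10.5         # µm, right boundary
    D1: float = 0.02         # µm²/s, cluster diffusion
    D2: float = 0.2          # µm²/s, particle diffusion
    a1: float = 1.029        # s⁻¹, S1 production amplitude
    a2: float = 0.441        # s⁻¹, S2 production amplitude
    a3: float = 0.26         # s⁻¹, fragmentation S1 -> S2
    a4: float = 0.049        # s⁻¹, aggregation S1 + S2 -> 2 S1
    a5: float = 0.035        # s⁻¹, dissociation S2 -> 0
    a6: float = 0.1089       # production profile width parameter
    dx: float = 0.035        # µm
    dt: float = 5e-4         # s

    def __post_init__(self) -> None:
        if self.K != 40:
            raise ValueError("the pom1p model is defined on K=40 compartments")
        for f in ("h", "D1", "D2", "a1", "a2", "a3", "a4", "a5", "a6"):
            if getattr(self, f) <= 0:
                raise ValueError(f"pom1p parameter {f} must be positive")

    def production_profile(self) -> np.ndarray:
        """Gaussian profile exp(-a6 (k - (K+1)/2)²) over compartments."""
        k = np.arange(1, self.K + 1)
        return np.exp(-self.a6 * (k - (self.K + 1) / 2) ** 2)


def pom1p_model(alpha: int = 10, params: Pom1pParams = Pom1pParams()):
    """pom1p model with species-specific partitions and two interfaces.

    S1 uses the SPDE description on compartments 11..30 (between I1=3.5 µm
    and I2=10.5 µm) and the Markov description elsewhere; S2 is Markov
    everywhere.  Reactions involving both species are simulated as jump
    events in the whole domain; inside the S1 SPDE region their S1 update is
    spread as +-1/alpha over the compartment's mesh cells while S2 changes
    by an integer.  Initial state is empty; the gradient forms dynamically.
    """
    p = params
    dom = Domain(L=p.L, K=p.K, h=p.h)
    profile = p.production_profile()
    reactions = [
        ReactionSpec.zeroth("production_S1", {"S1": +1}, p.a1, profile=profile),
        ReactionSpec.zeroth("production_S2", {"S2": +1}, p.a2, profile=profile),
        ReactionSpec.first("fragmentation", "S1", {"S1": -1, "S2": +1}, p.a3),
        ReactionSpec.second("aggregation", ("S1", "S2"),
                            {"S1": +1, "S2": -1}, p.a4),
        ReactionSpec.first("dissociation", "S2", {"S2": -1}, p.a5),
    ]
    init = np.zeros((2, p.K), dtype=np.int64)
    model = build_model(dom, [SpeciesSpec("S1", p.D1), SpeciesSpec("S2", p.D2)],
                        reactions, init)
    k1 = int(round(p.I1 / p.h))   # 10
    k2 = int(round(p.I2 / p.h))   # 30
    s1_blocks = (("markov", 1, k1), ("spde", k1 + 1, k2), ("markov", k2 + 1, p.K))
    partition = Partition(blocks=s1_blocks, alpha=alpha,
                          per_species={"S2": (("markov", 1, p.K),)})
    return model, partition


def apply_hybrid_reaction(state: HybridState, model: ReactionDiffusionModel,
                          reaction: str | int, k: int) -> HybridState:
    """Apply one fired reaction event in 1-based compartment ``k``.

    In compartments where a species is SPDE-represented its net change z is
    spread as z/alpha over the alpha mesh cells; Markov-represented species
    change by integers.  Total mass bookkeeping matches the stoichiometry
    exactly.
    """
    if isinstance(reaction, str):
        names = [r.name for r in model.reactions]
        reaction = names.index(reaction)
    r = model.reactions[reaction]
    new = state.copy()
    for name, z in r.stoich.items():
        if z == 0:
            continue
        i = model.species_index(name)
        if state.region[i, k - 1] == SPDE:
            new.grid[i, k - 1, :] += z / state.alpha
        else:
            new.comp[i, k - 1] += z
    return new


FIXTURES = {
    "morphogen": morphogen_model,
    "two_compartment": two_compartment_model,
    "pom1p": pom1p_model,
}
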