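# Methods

## Model class

`hybridrd` simulates stochastic reaction–diffusion kinetics on an elongated
pseudo-one-dimensional domain `Ω = [0, L] × [0, h_y] × [0, h_z]` divided into
`K` well-mixed compartments of length `h`.  The reference description is the
reaction–diffusion master equation (RDME): copy numbers `Z_i^k(t)` evolve by
reaction events with mass-action propensities `λ_j^k(Z^k)` and by diffusion
jumps between neighbouring compartments at per-molecule rate `D_i/h²`.  The
Gillespie direct method samples this process exactly: waiting time
`τ = −log(r₁)/a₀` from the total propensity `a₀`, event selection with
probability proportional to each propensity, in a fixed enumeration order
(reactions by reaction then compartment, then left jumps, then right jumps)
so that trajectories are bit-reproducible given a seed.

Where copy numbers are large the same jump process is well approximated by a
chemical-Langevin / stochastic-PDE description.  On a mesh of size
`dx = h/α` the discretized SPDE is advanced by an explicit Euler–Maruyama
step: for every interior mesh face a drift `D Δt/dx² (X^k − X^{k−1})` and a
single shared Gaussian increment of variance
`D Δt/dx² (X^k + X^{k−1}) χ{X^k + X^{k−1} ≥ 0}`, applied with opposite signs
to the two cells.  Sharing one increment per face makes the diffusion
operator conserve mass exactly, step by step; the indicator only guards the
square root.  Mesh values are real-valued and may transiently become
negative; they are never clamped.  Reactions whose participating species are
all mesh-resolved in a compartment contribute cell-local Langevin terms:
drift `λ_cell Δt` and noise `sqrt(max(λ_cell, 0) Δt)` per cell, where the
compartment rate of a zeroth-order reaction is split uniformly over the α
cells — or placed entirely in the first mesh interval for a flux-type
boundary source — and first-order rates act on the cell contents.
Second-order reactions are never given a Langevin form: wherever they occur
they are simulated as jump events (see the two-species model below).

## Hybrid coupling

A partition assigns each compartment, per species, to the SPDE or the Markov
description.  Two interface couplings are implemented.

**Scheme 1 (pseudo-compartment).**  The compartment-sized strip of mesh next
to the interface acts as a virtual compartment: a molecule in the boundary
Markov compartment jumps into it at rate `D/h²`, landing in a uniformly
chosen mesh cell (`point` mode) or spread as `+1/α` over all its cells
(`distributed` mode); the reverse transfer fires at rate `D/h²` times the
summed mesh mass of the strip, guarded to be at least 1, and removes the
molecule from a uniformly chosen cell (or `−1/α` from every cell).

**Scheme 2 (matched rates, no overlap).**  Transfers couple only the last
mesh cell and the boundary compartment, at rates `Ψ₁ D/h²` (in) and
`Ψ₂ D/dx² · max(X_edge, 0)` (out) with the finite-volume-matched factors
`Ψ₁ = 2h/(dx+h)`, `Ψ₂ = 2dx/(dx+h)`; at uniform concentration the two mean
fluxes are identical (`2Dc·h_y h_z/(dx+h)`).  The outgoing propensity is
guarded against negative edge-cell values only (`edge_guard = 0`); a strict
variant that refuses to transfer unless a whole molecule is present
(`edge_guard = 1`, so the −1 update itself can never drive the cell
negative) is selectable and discussed below.

The coupled loop interleaves SSA events with EM updates at fixed multiples
of Δt, processing whichever comes first (ties resolve in favour of the SSA
event).  Because interface-transfer and cross-species reaction propensities
depend on mesh values that change at every EM update, the pending event time
is by default redrawn, memorylessly, from the refreshed total propensity
after each EM step.  For piecewise-constant rates this sampling is exact.
The strictly frozen event clock (propensities and the pending waiting time
held fixed between Markov events, as a literal reading of the published
pseudocode suggests) is available as `redraw_after_spde=False`; it is
adequate for Scheme 1, whose outgoing rate tracks the slowly varying strip
total, but for Scheme 2 at fine meshes it decouples the transfer from the
fluctuating edge cell and produces severe spurious under-transfer (we
measured Markov-side means of ~10 instead of 25 on the two-compartment
benchmark at α = 30).  The refreshed clock is therefore the default.

### Stability

The explicit EM step requires `D Δt/dx² ≤ 1/2`.  The simulator warns at
build time when the bound is violated and aborts with a diagnostic when the
total propensity diverges (a blown-up mesh drives interface rates, and hence
the event frequency, toward infinity).  With the default Δt = 5·10⁻⁴ s and
`D = 0.8 µm²/s`, meshes up to α = 25 per 1 µm compartment are stable
(`D Δt/dx² = 0.25`); α = 40 and 50 are not (0.64 and 1.0), and runs there
terminate with the stability error rather than returning numbers.

### Interface bias at fine meshes, and the choice of edge guard

Scheme 2's accuracy hinges on how the outgoing propensity treats an edge
cell holding less than one molecule — routine at fine meshes, where the
mean occupancy per cell is the compartment count divided by α.  Because the
cell fluctuates (and may be negative), the realized mean flux is an
expectation over a truncated distribution, and the truncation point
matters to first order:

* **guard at 0** (default): the rate follows `max(X, 0)`.  Discarding only
  the negative excursions *raises* the mean above `E[X]` once
  `P(X < 0)` is appreciable — mildly at α = 10 (+7% flux on the morphogen
  benchmark, interface means within ~1% of exact), strongly at α = 25
  (+21% flux).  Scheme 2 therefore stays inside the 4% error band up to
  α = 10 and breaks out of it at α = 25 by *over*-transfer that nearly
  flattens the exact decreasing profile across the interface
  (means ≈10.6 / 10.0 against 11.8 / 9.2).
* **guard at 1** (strict): the transfer never acts on a sub-molecule cell,
  which protects the cell from transfer-induced negativity but truncates
  the flux the other way (`E[X χ{X≥1}] < E[X]` for Poisson-scale
  fluctuations): already at α = 10 this starves the Markov side by ~10%
  systematically, and at α = 25 the interface gradient steepens to
  ≈13.4 / 7.4.

The default follows the documented quantitative behaviour of the scheme
(accurate through α = 10, over-transfer bias at α = 25); the strict guard
is retained for sensitivity analysis.  Either way the lesson is the same
and is the method's central diagnosis: Scheme 2's single-cell coupling
becomes unreliable when `dx` is so fine that the edge cell holds less than
about one molecule.  Scheme 1, whose outgoing rate senses the
pseudo-compartment *total* (a quantity of order the compartment count,
with its own `≥ 1` guard rarely binding), stays within the band at every
stable mesh tested.

## Moving interface

The adaptive variant re-examines the interface every `n_c` EM steps: if the
pseudo-compartment strip holds fewer than `Q_lower` molecules it reverts to
the Markov description (mesh mass summed and rounded to the nearest integer,
clamped at zero — the rounding defect is at most 0.5 molecules per
conversion and is logged); otherwise, if the boundary compartment exceeds
`Q_upper`, it is promoted to the mesh description with its molecules spread
uniformly over the α cells (exactly mass-conserving).  At most one move of
±h occurs per check; the interface is clamped to `[0, L−h]`.  Adaptive
Scheme 1 runs force the `distributed` transfer mode: with point transfers
the repeated convert/transfer cycle at a moving interface fails to build the
correct gradient level.  After a move the event clock is redrawn (the event
set itself has changed).  Runs start fully compartment-based (`I(0) = 0`)
unless configured otherwise.

## Analytic moment oracle

For networks whose propensities are affine in the state (orders 0 and 1;
diffusion jumps are first-order in the donor compartment), the mean vector
and covariance matrix of the full Markov chain obey closed linear ODEs,

    dm/dt = A m + b,      dC/dt = A C + C Aᵀ + Σ_r ζ_r ζ_rᵀ λ_r(m),

assembled over the `N·K`-dimensional flat state and integrated with LSODA at
`rtol 1e-10, atol 1e-12`, so the oracle error is negligible against any
Monte-Carlo error in this package.  Models containing second-order reactions
are rejected (`moments do not close`); for those, the exact reference is the
full SSA.  A brute-force enumerator of the truncated master equation
(`cme_enumerate`) provides an independent cross-check on toy systems; its
stationary solver restricts to the class reachable from the initial state so
that conservation laws (pure diffusion) do not make the problem singular.

## Error metrics

Ensembles are compared to the Markov-chain reference per compartment:
`e_m(k) = 1 − E[aggregated]/E[Z^k]` and `e_v(k) = 1 − σ[aggregated]/σ[Z^k]`,
where a mesh compartment's α cells are summed within each realization before
statistics are taken (so the metric is invariant to how mass is split among
the cells).  Compartments with zero reference mean or sd are reported as
undefined and excluded from maxima.

## Packaged models and study conditions

* **Morphogen gradient**: one species, `L = 20 µm`, `K = 20`, `h = h_y =
  h_z = 1 µm`, `D = 0.8 µm²/s`, degradation `0.05 s⁻¹` everywhere, and a
  boundary source of flux density `25 µm⁻² s⁻¹` through the `h_y × h_z`
  face, i.e. a compartment propensity of `25 s⁻¹` in compartment 1 — placed
  in the first mesh interval inside the SPDE region, so that the
  deterministic limit satisfies `−D ∂c/∂x|₀ = J`.  Static-interface studies
  start with 500 molecules uniform over the left half and split the domain
  at `I = L/2`; moving-interface studies start empty.  `Δt = 5·10⁻⁴ s`,
  default `α = 5` (`dx = 0.2 µm`).
* **Two-compartment diffusion**: the same setting reduced to `K = 2` with
  no reactions and 50 molecules starting on the SPDE side; the exact
  stationary law of either compartment is Binomial(50, 1/2).
* **pom1p gradient**: two species on `L = 14 µm`, `K = 40`, `h = 0.35 µm`:
  slow clusters S1 (`D = 0.02 µm²/s`) and fast particles S2 (`0.2 µm²/s`),
  produced along a Gaussian profile centred mid-domain, with fragmentation
  `S1 → S2` (0.26 s⁻¹), second-order aggregation `S1 + S2 → 2 S1`
  (0.049 s⁻¹) and dissociation `S2 → ∅` (0.035 s⁻¹).  S1 is mesh-resolved
  on compartments 11–30 (between 3.5 and 10.5 µm, two static interfaces,
  `dx = 0.035 µm`); S2 is compartment-based everywhere.  Reactions
  involving both species are simulated as jump events in the whole domain;
  inside the S1 mesh region their S1 update is applied as ±1/α to every
  cell of the compartment while S2 changes by integers, which conserves
  S1+S2 exactly per event.  The initial state is empty (the published
  source does not state one; the gradient forms dynamically).

## What the tests show — and what they do not

The synthetic benchmarks exercise exactly the regimes above: linear or
weakly nonlinear kinetics, quasi-1-D geometry, moderate copy numbers.
Passing them shows the coupling transmits both the mean and the variance of
the underlying Markov chain across the interface — not that the CLE/SPDE
description is adequate for arbitrary real systems.  In particular, where a
mesh region holds well under one molecule per compartment the description is
outside its validity: on the pom1p model at `t = 50 s` the S1 profile has
not yet filled the mesh region, its edge compartments hold 0.05–1 molecules,
and the clamped reaction propensity on a fluctuating, sometimes-negative
strip total (`a₃ max(ΣX, 0)`) removes mass at a rate exceeding the linear
one (Jensen), leaving a persistent deficit of ~0.3–0.5 molecules there.
Compartments whose reference occupancy exceeds about 1.5 molecules agree
with the full SSA within 3 combined standard errors at 200+200
realizations; the near-empty edge compartments do not, at any ensemble size,
because the bias is real and the standard error shrinks.  Practical use of
the method should place interfaces where occupancies are comfortably above
one molecule per mesh compartment.

## Numerical choices

* Fixed explicit EM step (no adaptivity), default `Δt = 5·10⁻⁴ s`.
* Reaction propensities evaluated on mesh aggregates are clamped at 0
  before use (event sampling needs non-negative rates; the diffusion noise
  uses the pair-sum indicator instead, as specified by the scheme).
* Event-selection ties and `t_m = t_s` ties resolve deterministically
  (SSA event first).
* Trajectories are recorded at the requested times with the state that the
  last update at or before that time produced; a time-zero record returns
  the initial state.
* If the total propensity vanishes the state is absorbing and remaining
  record times repeat it.
* Two SFC64 streams per realization (Gaussian increments; uniforms for
  event timing, selection and placement), spawned from one `SeedSequence`,
  give bit-identical trajectories for identical seeds, independent of
  internal block sizes.  Ensemble sweeps that compare interface schemes run
  both schemes on the same per-realization Gaussian stream (common random
  numbers); each ensemble's marginal statistics are unaffected.

## Ensemble sizes used in the shipped checks

Published-scale ensembles (10⁴ realizations) are scaled to desk runtimes;
Monte-Carlo allowances in the assertions widen accordingly (3 SE of the
relevant estimator).  The test suite uses 100 realizations for the
two-compartment benchmark (as published), 400 per scheme for the
static-interface morphogen comparison, 150–250 per mesh refinement in the
α sweep, 100–120 per configuration for the moving-interface checks and
200+200 for the pom1p comparison.  The acceptance script uses 100, 1000 per
scheme, and 400–800 per sweep configuration.
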