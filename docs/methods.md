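# Methods

`lc8bridge` models the thermodynamics and equilibrium composition of the
complexes that the dynein light chain LC8 forms with the C-terminal region
of 53BP1 (its LC8-binding domain, LBD, followed by a trimeric
oligomerization domain, OD). Each 53BP1 chain carries up to three short LC8
recognition ("QT") motifs; an LC8 homodimer has two symmetric grooves and
cross-links two client chains — either two chains of the same 53BP1 trimer
(*intratrimer* binding) or chains from two different trimers (*bridging*),
producing a dimer-of-trimers. The package implements four connected pieces:
forward ITC models, inverse fitting with replicate aggregation,
composition-to-mass bookkeeping, and mass-action speciation.

## Units and constants

Energies in kcal/mol with R = 1.987204×10⁻³ kcal/(mol·K); concentrations in
molar; volumes in liters; masses in kDa; heats in µcal (1 kcal = 10⁹ µcal).
Default temperature 298.15 K (25 °C). ΔG = RT·ln(K_d) (negative for
favorable binding) and −TΔS = ΔG − ΔH, so ΔG = ΔH + (−TΔS) holds by
construction.

## Forward ITC models

**Concentration accounting.** A perfusion cell of volume V₀ overflows as
titrant is injected. After cumulative injected volume v, the symmetric
half-volume convention gives cell-species and titrant totals

    M_t = M₀ (1 − v/2V₀)/(1 + v/2V₀),   X_t = X_s (v/V₀)/(1 + v/2V₀).

Any self-consistent convention shifts fitted association constants by <1 %
at these volumes; this one matches common instrument practice.

**One set of sites (OSS).** Total heat content after an injection follows
the Wiseman closed form

    Q = (n·M_t·ΔH·V₀/2)·[1 + r + s − √((1 + r + s)² − 4r)],

with r = X_t/(n·M_t), s = 1/(n·K_a·M_t). Per-injection heats apply the
displacement correction ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2 (a flag
disables it for idealized tests), and normalized heats divide by the moles
injected. The closed form is verified in the test suite against an
independent bisection solution of the binding mass balance to 10⁻⁹
relative.

**Sequential binding sites (SBS).** The macromolecule is the 53BP1
*hexamer* (dimer-of-trimers equivalent: cell trimer concentration ÷ 2),
binding three LC8 dimers in ordered events with stepwise association
constants k₁–k₃ and enthalpies h₁–h₃; events 1–2 are the intratrimer
additions, event 3 the bridging one. State populations come from the
binding polynomial F_j ∝ β_j L^j with β_j = Πᵢ≤j kᵢ, and the free ligand L
solves X_t = L + M_t·Σ j·F_j by bracketed Brent iteration on [0, X_t]
(residual < 10⁻¹²·X_t; the residual is monotone so convergence is
guaranteed). Total heat is Q = M_t·V₀·Σ F_j·(Σ_{e≤j} h_e). With k₂ = k₃ = 0
the model reduces exactly to the n = 1 OSS model, which the tests exploit
as a cross-check.

**Titration-order dependence.** `sequential_isotherm(..., reverse_roles=True)`
swaps the roles (macromolecule in the syringe, ligand in the cell),
emulating the reversed experiments used to test for intermediates. Shape is
scored by `count_phases`, which counts sign changes of the second
difference of the normalized-heat curve after discarding changes below 2 %
of the curve's amplitude: a single sigmoid scores ≤ 1, a two-phase curve
with a visible intermediate ≥ 2. The shape demonstration in the tests uses
a well-separated affinity pair (0.01 µM intratrimer, 0.5 µM bridging) and a
45 × 12 µL schedule so both transitions complete within the titration
window; with gentler separation the two transitions blend into a single
apparent phase under this metric, which is itself an illustration of why
reversed titrations are informative.

## Inverse problem

**OSS fits** estimate (n, ln K_a, ΔH), optionally plus a constant
per-injection dilution-offset, by trust-region least squares on normalized
heats. K_a is optimized in log space because it spans decades. Starting
values use standard heuristics — ΔH from the first-injection plateau, n
from the molar-ratio position of the steepest heat change, K_a from the
transition width — backed by log-spaced K_a multi-starts. Standard errors
come from the Jacobian at the optimum (σ² = RSS/dof). A flat isotherm is
returned flagged ill-conditioned rather than producing a spurious affinity.
Parameter recovery on noiseless data is exact to ≲10⁻⁶ relative across the
identifiable Wiseman range c = n·K_a·M_t ∈ [5, 500].

**Constrained sequential fits** enforce the hexamer constraint set — two
identical intratrimer events and a distinct bridging event: k₁ = k₂,
h₁ = h₂, k₁ > k₃, h₁ < h₃. Equalities are imposed by parameter sharing and
the strict orderings by the smooth reparametrization k₃ = k₁·e^(−δ²),
h₃ = h₁ + ε² with δ, ε free, which keeps the problem differentiable and
makes every iterate feasible; an infeasible initial guess is projected into
the feasible region. Five jittered multi-starts (sub-seeded from the `seed`
argument) guard against local minima. Fits whose affinities are uncertain
beyond a factor e, or whose bridging enthalpy error swamps the h₃ − h₁ gap,
are flagged ill-conditioned — this is the expected outcome when
single-event data are force-fit with the three-event model. No measured
bridging enthalpy is available, so the synthetic ground truth used in
recovery tests (h₁ = h₂ = −10, h₃ = −5 kcal/mol) is a package choice
satisfying the constraints.

**Derived thermodynamics** (ΔG, −TΔS per event) are computed per replicate
with first-order error propagation (σ_ΔG = RT·σ_Kd/K_d), and replicates are
then aggregated; derive-then-aggregate is the package's convention.

**Inverse-variance aggregation** is implemented verbatim as
ŷ = Σ(yᵢ/σᵢ²)/Σ(1/σᵢ²) with aggregate error σ̂ = 1/Σ(1/σᵢ²). Note the
printed error rule returns a variance-scale quantity; `conventional=True`
returns its square root (the standard error of the weighted mean). The
package keeps the variance-scale rule as the default and exposes the flag
for conventional reporting.

## Composition and mass bookkeeping

Complexes are described by (number of trimers ∈ {1, 2}, number of bound LC8
dimers, q) where q ∈ {1, 2, 3} is the count of intact QT motifs per chain.
The architecture is hard-coded: 3 chains per trimer, one LC8 dimer spanning
2 chains, giving maximal occupancies q (single trimer) and 3q
(dimer-of-trimers) and expected masses n_trimers·3·17.0 + n_LC8·21.2 kDa
with the default monomer masses (LBD-OD protomer 17.0, LC8 dimer 21.2, bare
OD protomer 13.2 kDa; all configurable). The package always computes masses
from the mass table rather than reproducing independently rounded figures —
e.g. 3 × 13.2 gives 39.6 kDa for the OD trimer even where a 39.5 kDa figure
(implying an unrounded monomer mass) is in circulation, and a "dimeric
LBD-OD + 3 LC8" complex sums to 97.6 kDa, not the sometimes-quoted 95.
`assign_composition` maps a measured SEC-MALS mass
to the nearest enumerated composition (ties toward fewer LC8); it reports
distance-to-nearest only and does not assert identity, since partially
occupied bridged species and 53BP1 dimer/tetramer states can be
mass-degenerate.

`enumerate_species(q)` lists the observable ladder with bridged occupancy
from q (all bridging positions filled, no intratrimer LC8) to 3q — for
q = 3, bridged species carrying 3–9 LC8 dimers. The mass-action solver
below additionally populates partially bridged intermediates (down to a
single bridging LC8); `enumerate_species(q, min_occupancy=1)` exposes that
full ladder.

## Mass-action speciation

Each QT-motif position across a trimer's chains is a *register*. Per
register a trimer hosts at most one intratrimer LC8 (occupying 2 of 3
chains); in a two-trimer pair the leftover chain of each trimer can be
joined by one bridging LC8 — at most 3 LC8 per register, reproducing the
1:q and 2:3q stoichiometries. Registers are independent (whether and how
they interact is unresolved experimentally; independence is the minimal
assumption and is recorded in output metadata via the model object).

Species statistical weights are generating-function products over
registers, with x = [LC8]/K_intra and y = [LC8]/K_bridge:

    single trimer:   (1 + 3x)^q
    bridged pair:    [(1 + 3x)² + 9y(1 + x)²]^q  minus the no-bridge term

The 3 counts intratrimer placements (chain-pair choice) and the 9 bridging
placements (one chain on each trimer); `degeneracy=False` drops these
statistical factors for use with fitted constants that already absorb
degeneracy. Because forming a bridged pair is bimolecular in trimer, the
first bridging LC8 carries an additional factor 1/K_bridge (units 1/M): its
second groove captures a chain of a free second trimer at the same
per-event affinity, while subsequent bridges close intramolecular rings and
enter only through the dimensionless y. Without this factor the additive
prescription implicitly divides by a 1 M standard state and suppresses
bridged species by ~10⁵ at µM concentrations.

The two unknowns (free trimer t, free LC8 ℓ) satisfy two conservation laws.
At fixed ℓ, t solves a quadratic with a closed-form positive root; ℓ is
then bracketed in [0, total LC8] and solved by Brent iteration at machine
precision. Conservation of both totals holds to 10⁻⁹ relative (checked at
every solver exit and on 1,000 random scenarios in the tests). Higher 53BP1
oligomers (dimers, tetramers) are excluded, mirroring the simplification to
trimer-based populations. K_bridge = ∞ switches bridging off, reducing the
model to independent-register intratrimer binding with a closed-form bound
fraction (a tested limit).

`mass_profile` converts a speciation state to SEC-MALS-style observables:
weight fractions ∝ concentration × mass and weight-average mass
Σcᵢmᵢ²/Σcᵢmᵢ. `titration_profile` speciates along an LC8 titration
(equivalents are LC8 dimers per 53BP1 trimer).

## Synthetic data

The generator emulates VP-ITC titrations of the modeled experiments:
syringe species at 250–400 µM into cell species at 10–35 µM; defaults
28 × 10 µL injections into a 1.4 mL cell at 25 °C (injection count,
injection volume and cell volume are package conventions).
Gaussian noise of sd σ (default 0.1 µcal, a package convention calibrated
so that replicate aggregation is statistically consistent) is applied to
the *raw* per-injection heats, since instrument noise is per injection and
normalization rescales it by injected moles. Determinism: one integer
master seed; replicate r uses sub-seed seed + r through NumPy's
`default_rng`. Presets named after the constructs carry the corresponding
fitted OSS parameters, and `qt2-od-sbs` carries the sequential
intratrimer/bridging pair (0.3 µM / 1.1 µM).

What the generator does *not* emulate: baseline drift, peak-integration
error, heats of dilution beyond an optional constant offset, titrant or
cell concentration errors, and temperature fluctuations. Passing recovery
tests therefore demonstrate the correctness and conditioning of the
estimators under the stated noise model, not robustness to every real
instrument artifact.

## Problem sizes and numerical choices

Test and acceptance runs use 25–40 replicate fits of 28-point isotherms,
1,000-draw oracle-equivalence and conservation sweeps, and grid-oracle
cross-checks at ~10⁻⁴ relative resolution; all complete in well under a
minute apiece. Root solvers use bracketed Brent iteration at machine
tolerance; least squares uses `scipy.optimize.least_squares` (trust-region
reflective) with xtol = ftol = 10⁻¹⁴ or tighter. Degenerate inputs (flat
isotherms, zero totals, zero noise) are handled explicitly and tested.

## Known limitations

- The sequential fitter supports exactly the hexamer constraint structure
  (k₁ = k₂, h₁ = h₂, k₁ > k₃, h₁ < h₃); other constraint graphs are
  rejected rather than approximated.
- Speciation is equilibrium-only; no kinetics, and no prediction of
  sedimentation coefficients — compositions are compared to experiment by
  mass only.
- The bridging bimolecularity convention above is a modeling choice; fitted
  K_bridge values from the ITC module and the speciation K_bridge are
  commensurate only up to that convention and the statistical-factor mode.
- No global multi-isotherm fitting: replicates are fit independently and
  aggregated, matching the replicate-then-aggregate workflow the package
  models.
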