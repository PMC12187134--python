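"""Mass-action speciation of LC8-bridged 53BP1 trimer assemblies.

Geometry.  Each 53BP1 chain carries q intact QT recognition motifs
(q = 1, 2 or 3); the motif at a given sequence position across the chains
of a trimer is called a *register*.  Per register, a trimer can host one
intratrimer LC8 dimer (cross-linking 2 of its 3 chains), and in a
two-trimer complex the leftover chain of each trimer can be joined by one
bridging LC8 dimer — so a register holds at most 2 intratrimer + 1 bridging
LC8 and a dimer-of-trimers at most 3q, reproducing the 1:q and 2:3q
stoichiometries of the fully occupied trimer and bridged complexes.

Energetics.  Species free energies are additive over bound LC8: every
intratrimer event contributes a factor [LC8]/kd_intra and every bridging
event [LC8]/kd_bridge.  With statistical degeneracy on (the default), an
intratrimer LC8 has 3 placements (choice of chain pair) and a bridging LC8
9 (choice of chain on each trimer); when an intratrimer LC8 shares a
register with a bridge the free chain is forced, and the per-register count
works out to 9 configurations for every bridge-containing state.  Register
generating functions (x = [LC8]/kd_intra, y = [LC8]/kd_bridge):

    single trimer, per register:   1 + 3x
    bridged pair, per register:    (1 + 3x)^2 + 9y(1 + x)^2

(with degeneracy off the 3s and 9s become 1s).  A species is *bridged* when
at least one register carries a bridging LC8; the no-bridge term is
subtracted since it is just two independent trimers.  Because forming a
bridged pair is bimolecular in trimer, the first bridging LC8 contributes
an additional factor 1/kd_bridge (units 1/M) beyond its dimensionless site
factor y: its second groove captures a chain of a *free* second trimer at
the same per-event affinity, while subsequent bridges close intramolecular
rings and enter only through y.

The two unknowns (free trimer, free LC8 dimer) are solved from the trimer
and LC8 conservation laws: free trimer has a closed-form root of a
quadratic at fixed free LC8, and free LC8 is bracketed by Brent iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SolverError
from .thermo import MassTable, SpeciesComposition, complex_mass, max_occupancy


@dataclass(frozen=True)
class LadderModel:
    """Two-affinity model of intratrimer and bridging LC8 binding.

    ``kd_intra`` and ``kd_bridge`` are per-event dissociation constants in
    molar; ``degeneracy`` toggles the per-register statistical factors
    (disable it when using fitted constants that already absorb degeneracy).
    ``kd_bridge = math.inf`` turns bridging off entirely.
    """

    q: int
    kd_intra: float
    kd_bridge: float
    degeneracy: bool = True

    def __post_init__(self):
        if self.q not in (1, 2, 3):
            raise DomainError(f"q must be 1, 2 or 3, got {self.q}")
        if not (self.kd_intra > 0) or not (self.kd_bridge > 0):
            raise DomainError("dissociation constants must be strictly positive")


@dataclass
class SpeciationState:
    """Equilibrium concentrations of every enumerated species.

    ``species`` maps compositions to molar concentrations; free trimer and
    free LC8 dimer are carried separately.  Conservation of both totals is
    checked at construction to 1e-9 relative.
    """

    species: list  # list[(SpeciesComposition, float)]
    free_trimer: float
    free_lc8: float
    total_trimer: float
    total_lc8: float
    model: LadderModel

    def __post_init__(self):
        if any(c < 0 for _, c in self.species) or self.free_trimer < 0 or self.free_lc8 < 0:
            raise DomainError("concentrations must be non-negative")
        t = self.free_trimer + sum(comp.n_trimers * c for comp, c in self.species)
        l = self.free_lc8 + sum(comp.n_lc8_dimers * c for comp, c in self.species)
        scale_t = max(self.total_trimer, 1e-300)
        scale_l = max(self.total_lc8, 1e-300)
        if abs(t - self.total_trimer) > 1e-9 * scale_t:
            raise SolverError("trimer conservation violated", residual=t - self.total_trimer)
        if abs(l - self.total_lc8) > 1e-9 * scale_l:
            raise SolverError("LC8 conservation violated", residual=l - self.total_lc8)

    def concentration(self, n_trimers: int, n_lc8: int) -> float:
        """Concentration of one composition (0 if not populated)."""
        for comp, c in self.species:
            if comp.n_trimers == n_trimers and comp.n_lc8_dimers == n_lc8:
                return c
        if (n_trimers, n_lc8) == (1, 0):
            return self.free_trimer
        return 0.0

    def bridged_fraction(self) -> float:
        """Fraction of trimers incorporated in two-trimer species."""
        bridged = sum(2 * c for comp, c in self.species if comp.n_trimers == 2)
        return bridged / self.total_trimer if self.total_trimer > 0 else 0.0


def enumerate_species(q: int, min_occupancy: int | None = None) -> list[SpeciesComposition]:
    """Enumerate the complexes of the trimer/bridged ladder for a given q.

    Returns the free trimer, the partially to fully occupied single-trimer
    complexes (1:1 .. 1:q), and the bridged dimer-of-trimers species
    (2:m for m = min_occupancy .. 3q).  ``min_occupancy`` defaults to q,
    the occupancy with every bridging position filled and no intratrimer
    LC8 — for q = 3 the bridged species then span 3 to 9 LC8 dimers.
    """
    if q not in (1, 2, 3):
        raise DomainError(f"q must be 1, 2 or 3, got {q}")
    m_min = q if min_occupancy is None else min_occupancy
    if not (1 <= m_min <= 3 * q):
        raise DomainError(f"min_occupancy must be in [1, {3 * q}]")
    trimer_max, bridged_max = max_occupancy(q)
    out = [SpeciesComposition(1, 0, q)]
    out += [SpeciesComposition(1, j, q) for j in range(1, trimer_max + 1)]
    out += [SpeciesComposition(2, m, q) for m in range(m_min, bridged_max + 1)]
    return out


def _coeff(a: int, c: int, i: int) -> int:
    """Coefficient of x^i in (1+x)^a * (1+3x)^c."""
    total = 0
    for j in range(max(0, i - c), min(a, i) + 1):
        total += math.comb(a, j) * math.comb(c, i - j) * 3 ** (i - j)
    return total


def _bridged_pattern_count(q: int, i: int, b: int, degeneracy: bool) -> float:
    """Number of configurations of a bridged pair with i intratrimer and b
    bridging LC8, including statistical factors when ``degeneracy`` is on.

    Registers with a bridge contribute (per-register) 9y(1+x)^2 and those
    without (1+3x)^2; picking which b of the q registers are bridged gives
    the binomial prefactor.
    """
    if not (1 <= b <= q) or not (0 <= i <= 2 * q):
        return 0.0
    if degeneracy:
        return math.comb(q, b) * 9**b * _coeff(2 * b, 2 * (q - b), i)
    return math.comb(q, b) * math.comb(2 * q, i)


def _ladder_weights(model: LadderModel, x: float, y: float):
    """Polynomial weights of every species relative to free trimer.

    Returns (single, bridged): ``single[j]`` is the dimensionless weight of
    the trimer with j intratrimer LC8 (concentration = [T] * single[j]);
    ``bridged`` is a dict (i, b) -> weight with concentration
    = [T]^2 * weight, so bridged weights carry units of 1/molar: the first
    bridging LC8's capture of the second trimer is the bimolecular
    dimerization step and contributes an extra 1/kd_bridge beyond its
    dimensionless site factor y.
    """
    q = model.q
    g1 = 3.0 if model.degeneracy else 1.0
    single = {j: math.comb(q, j) * (g1 * x) ** j for j in range(q + 1)}
    dimerization = 1.0 / model.kd_bridge if math.isfinite(model.kd_bridge) else 0.0
    bridged = {}
    for b in range(1, q + 1):
        for i in range(0, 2 * q + 1):
            n = _bridged_pattern_count(q, i, b, model.degeneracy)
            if n:
                bridged[(i, b)] = n * x**i * y**b * dimerization
    return single, bridged


def speciate(
    total_trimer: float, total_lc8_dimer: float, model: LadderModel
) -> SpeciationState:
    """Equilibrium speciation at given total trimer and LC8-dimer inputs.

    Solves the coupled trimer and LC8 mass balances for the free
    concentrations, then populates every single-trimer and bridged species
    of the ladder (bridged species require at least one bridging LC8).
    """
    if total_trimer < 0 or total_lc8_dimer < 0:
        raise DomainError("totals must be non-negative")
    q = model.q

    def solve_free_trimer(ell: float) -> float:
        x = ell / model.kd_intra
        y = ell / model.kd_bridge if math.isfinite(model.kd_bridge) else 0.0
        single, bridged = _ladder_weights(model, x, y)
        p = sum(single.values())
        b_tot = sum(bridged.values())
        if b_tot == 0:
            return total_trimer / p
        # 2*B*t^2 + P*t - T_tot = 0
        disc = p * p + 8.0 * b_tot * total_trimer
        return (math.sqrt(disc) - p) / (4.0 * b_tot)

    def lc8_residual(ell: float) -> float:
        x = ell / model.kd_intra
        y = ell / model.kd_bridge if math.isfinite(model.kd_bridge) else 0.0
        t = solve_free_trimer(ell)
        single, bridged = _ladder_weights(model, x, y)
        bound = t * sum(j * w for j, w in single.items())
        bound += t * t * sum((i + b) * w for (i, b), w in bridged.items())
        return ell + bound - total_lc8_dimer

    if total_lc8_dimer == 0 or total_trimer == 0:
        ell = total_lc8_dimer if total_trimer == 0 else 0.0
    else:
        ell = brentq(
            lc8_residual, 0.0, total_lc8_dimer,
            xtol=1e-300, rtol=4 * np.finfo(float).eps, maxiter=300,
        )
    t = solve_free_trimer(ell)
    x = ell / model.kd_intra
    y = ell / model.kd_bridge if math.isfinite(model.kd_bridge) else 0.0
    single, bridged = _ladder_weights(model, x, y)

    species: list[tuple[SpeciesComposition, float]] = []
    for j in range(1, q + 1):
        species.append((SpeciesComposition(1, j, q), t * single[j]))
    by_m: dict[int, float] = {}
    for (i, b), w in bridged.items():
        by_m[i + b] = by_m.get(i + b, 0.0) + t * t * w
    for m in sorted(by_m):
        species.append((SpeciesComposition(2, m, q), by_m[m]))

    # re-enforce LC8 conservation exactly against solver round-off
    free_lc8 = total_lc8_dimer - sum(c.n_lc8_dimers * conc for c, conc in species)
    free_lc8 = max(free_lc8, 0.0)
    # cancellation in the subtraction can undershoot zero by ~eps * totals
    free_trimer = max(
        total_trimer - sum(c.n_trimers * conc for c, conc in species), 0.0
    )
    return SpeciationState(
        species=species,
        free_trimer=free_trimer,
        free_lc8=free_lc8,
        total_trimer=total_trimer,
        total_lc8=total_lc8_dimer,
        model=model,
    )


def mass_profile(
    state: SpeciationState,
    masses: MassTable | None = None,
    include_free: bool = True,
) -> tuple[list, float]:
    """Mass-weighted view of a speciation state for SEC-MALS interpretation.

    Returns ``(entries, weight_average_mass)`` where each entry is
    ``(composition, mass_kDa, weight_fraction)``; weight fractions are
    proportional to concentration x mass and the weight-average mass is
    ``sum(c m^2)/sum(c m)`` (between the lightest and heaviest populated
    species).  ``include_free`` adds free trimer and free LC8 dimer.
    """
    masses = masses if masses is not None else MassTable()
    q = state.model.q
    rows: list[tuple[SpeciesComposition, float, float]] = []
    items = list(state.species)
    if include_free:
        items.append((SpeciesComposition(1, 0, q), state.free_trimer))
        items.append((SpeciesComposition(0, 1, q), state.free_lc8))
    cm = [(comp, complex_mass(comp, masses), conc) for comp, conc in items]
    denom = sum(c * m for _, m, c in cm)
    if denom <= 0:
        raise DomainError("mass profile of an empty state")
    for comp, m, c in cm:
        rows.append((comp, m, c * m / denom))
    mw = sum(c * m * m for _, m, c in cm) / denom
    return rows, float(mw)


def titration_profile(
    equivalents, total_trimer: float, model: LadderModel
) -> list[SpeciationState]:
    """Speciate along an LC8 titration.

    ``equivalents`` are LC8-dimer:trimer molar ratios (non-negative,
    increasing); total LC8 dimer at each point is equivalents * total_trimer.
    """
    eq = list(equivalents)
    if any(e < 0 for e in eq) or any(b < a for a, b in zip(eq, eq[1:])):
        raise DomainError("equivalents must be non-negative and non-decreasing")
    return [speciate(total_trimer, e * total_trimer, model) for e in eq]


def assign_composition(
    measured_mass: float, q: int, masses: MassTable | None = None
) -> SpeciesComposition:
    """Nearest enumerated composition to a measured complex mass.

    Scans the full ladder (bridged occupancy down to a single LC8) and
    returns the composition minimizing |expected - measured|; ties break
    toward fewer LC8 dimers.  The assignment is distance-to-nearest only —
    it does not assert that the measured peak *is* that species.
    """
    if not (measured_mass > 0):
        raise DomainError("measured mass must be positive")
    masses = masses if masses is not None else MassTable()
    best = None
    for comp in enumerate_species(q, min_occupancy=1):
        d = abs(complex_mass(comp, masses) - measured_mass)
        key = (d, comp.n_lc8_dimers, comp.n_trimers)
        if best is None or key < best[0]:
            best = (key, comp)
    return best[1]
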