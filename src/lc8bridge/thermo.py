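"""Thermodynamic identities and composition-to-mass bookkeeping.

Units are fixed package-wide: energies in kcal/mol, concentrations in molar,
temperatures in kelvin, masses in kDa.  The gas constant is
``R = 1.987204e-3`` kcal/(mol K) and the default temperature is 298.15 K
(the 25 degC condition of the calorimetry experiments).

The composition model hard-codes the trimer architecture of the 53BP1
oligomerization domain: a 53BP1 protomer (LBD-OD) self-associates into a
trimer; an LC8 homodimer cross-links two client chains, either within one
trimer ("intratrimer") or across two trimers ("bridging"), so a complex is
described by (number of trimers, number of bound LC8 dimers).  With q intact
LC8 recognition (QT) sites per chain, a single trimer binds at most q LC8
dimers and a bridged dimer-of-trimers binds at most 3q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import CompositionError, DomainError

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987204e-3

#: Default experimental temperature (25 degC) in kelvin.
T_DEFAULT = 298.15


@dataclass(frozen=True)
class ThermoParams:
    """One-set-of-sites binding parameters.

    Parameters
    ----------
    n_sites:
        Stoichiometry N per macromolecule (dimensionless).
    kd:
        Dissociation constant in molar.
    dh:
        Binding enthalpy change in kcal/mol.
    temperature:
        Kelvin; defaults to 298.15 K.
    """

    n_sites: float
    kd: float
    dh: float
    temperature: float = T_DEFAULT

    def __post_init__(self):
        if not (self.kd > 0):
            raise DomainError(f"kd must be > 0, got {self.kd}")
        if not (self.temperature > 0):
            raise DomainError(f"temperature must be > 0, got {self.temperature}")
        if not (self.n_sites > 0):
            raise DomainError(f"n_sites must be > 0, got {self.n_sites}")

    @property
    def ka(self) -> float:
        """Association constant 1/kd in 1/molar."""
        return 1.0 / self.kd


@dataclass(frozen=True)
class DerivedThermo:
    """Derived free energy and entropic term, with optional propagated errors.

    By construction ``dg = dh + neg_t_ds``.
    """

    dg: float
    neg_t_ds: float
    dg_err: float = 0.0
    neg_t_ds_err: float = 0.0


@dataclass(frozen=True)
class MassTable:
    """Monomer/dimer masses in kDa used for expected-complex-mass bookkeeping.

    Defaults are the constructs' expected masses: the 53BP1 LBD-OD protomer
    (17.0), the LC8 homodimer (21.2) and the bare oligomerization-domain
    protomer (13.2).
    """

    lbd_od_monomer: float = 17.0
    lc8_dimer: float = 21.2
    od_monomer: float = 13.2

    def __post_init__(self):
        for name in ("lbd_od_monomer", "lc8_dimer", "od_monomer"):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "lbd_od_monomer_kDa": self.lbd_od_monomer,
            "lc8_dimer_kDa": self.lc8_dimer,
            "od_monomer_kDa": self.od_monomer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MassTable":
        return cls(
            lbd_od_monomer=float(d.get("lbd_od_monomer_kDa", 17.0)),
            lc8_dimer=float(d.get("lc8_dimer_kDa", 21.2)),
            od_monomer=float(d.get("od_monomer_kDa", 13.2)),
        )


@dataclass(frozen=True)
class SpeciesComposition:
    """Counts of 53BP1 trimers and bound LC8 dimers in one complex.

    ``q`` is the number of intact QT sites per chain (1-3).  Occupancy bounds
    follow the trimer architecture: a lone trimer hosts at most q LC8 dimers,
    a bridged dimer-of-trimers at most 3q.  ``n_trimers = 0`` describes free
    LC8 (used in mass profiles).
    """

    n_trimers: int
    n_lc8_dimers: int
    q: int = 3

    def __post_init__(self):
        if self.q not in (1, 2, 3):
            raise DomainError(f"q must be 1, 2 or 3, got {self.q}")
        if self.n_trimers not in (0, 1, 2):
            raise CompositionError(f"n_trimers must be 0, 1 or 2, got {self.n_trimers}")
        if self.n_lc8_dimers < 0:
            raise CompositionError("n_lc8_dimers must be non-negative")
        if self.n_trimers == 1 and self.n_lc8_dimers > self.q:
            raise CompositionError(
                f"a single trimer binds at most q={self.q} LC8 dimers, "
                f"got {self.n_lc8_dimers}"
            )
        if self.n_trimers == 2 and self.n_lc8_dimers > 3 * self.q:
            raise CompositionError(
                f"a dimer-of-trimers binds at most 3q={3 * self.q} LC8 dimers, "
                f"got {self.n_lc8_dimers}"
            )

    @property
    def ratio(self) -> str:
        """Stoichiometry ratio string, e.g. ``'2:9'``."""
        return f"{self.n_trimers}:{self.n_lc8_dimers}"


def delta_g_from_kd(kd: float, temperature: float = T_DEFAULT) -> float:
    """Gibbs free energy of binding, ``R*T*ln(kd)``, in kcal/mol.

    Negative for sub-molar dissociation constants (favorable binding); the
    sign convention matches standard calorimetry reporting.
    """
    if not (kd > 0):
        raise DomainError(f"kd must be > 0, got {kd}")
    if not (temperature > 0):
        raise DomainError(f"temperature must be > 0, got {temperature}")
    return R_KCAL * temperature * math.log(kd)


def kd_from_delta_g(dg: float, temperature: float = T_DEFAULT) -> float:
    """Inverse of :func:`delta_g_from_kd`."""
    if not (temperature > 0):
        raise DomainError(f"temperature must be > 0, got {temperature}")
    return math.exp(dg / (R_KCAL * temperature))


def neg_t_delta_s(dg: float, dh: float) -> float:
    """Entropic term -T*dS = dG - dH, in kcal/mol."""
    return dg - dh


def complex_mass(comp: SpeciesComposition, masses: MassTable | None = None) -> float:
    """Expected mass in kDa of a trimer/bridged complex.

    ``n_trimers * 3 * protomer + n_lc8_dimers * lc8_dimer``; the protomer
    mass is the LBD-OD monomer from ``masses``.
    """
    masses = masses if masses is not None else MassTable()
    return comp.n_trimers * 3 * masses.lbd_od_monomer + comp.n_lc8_dimers * masses.lc8_dimer


def max_occupancy(q: int) -> tuple[int, int]:
    """Maximum LC8-dimer occupancy of the trimer and bridged complexes.

    Returns ``(q, 3q)``: one LC8 dimer per intact QT register for a lone
    trimer, and three per register (two intratrimer plus one bridging) for
    the fully occupied dimer-of-trimers.
    """
    if q not in (1, 2, 3):
        raise DomainError(f"q must be 1, 2 or 3, got {q}")
    return q, 3 * q


def expected_mass_table(q: int, masses: MassTable | None = None) -> dict:
    """Expected masses of the fully occupied complexes for a given q.

    Returns a dict with the bridged (2:3q) and trimer (1:q) stoichiometry
    ratios and masses, plus the free-trimer mass.
    """
    masses = masses if masses is not None else MassTable()
    trimer_max, bridged_max = max_occupancy(q)
    bridged = SpeciesComposition(2, bridged_max, q)
    trimer = SpeciesComposition(1, trimer_max, q)
    free = SpeciesComposition(1, 0, q)
    return {
        "q": q,
        "bridged_ratio": bridged.ratio,
        "bridged_mass_kDa": round(complex_mass(bridged, masses), 1),
        "trimer_ratio": trimer.ratio,
        "trimer_mass_kDa": round(complex_mass(trimer, masses), 1),
        "free_trimer_mass_kDa": round(complex_mass(free, masses), 1),
    }
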