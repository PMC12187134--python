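"""Forward simulation of ITC titrations.

Implements per-injection concentration accounting with the symmetric
half-volume perfusion correction, the closed-form one-set-of-sites (OSS,
Wiseman) total heat, and a three-event sequential-binding-sites (SBS) model
evaluated through its binding polynomial.  The sequential model describes a
53BP1 hexamer (dimer-of-trimers equivalent) binding three LC8 dimers: two
intratrimer events with identical constants and one bridging event.

Heat bookkeeping: total heat content Q(i) after injection i is in kcal; the
per-injection differential heat applies the displacement correction

    dQ(i) = Q(i) - Q(i-1) + (dV_i / V0) * (Q(i) + Q(i-1)) / 2

and the normalized heat is dQ(i) per mole of injectant, in kcal/mol.
Raw heats are reported in ucal (1 kcal = 1e9 ucal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, ScheduleError, SolverError
from .thermo import T_DEFAULT, ThermoParams

#: ucal per kcal.
UCAL_PER_KCAL = 1e9


@dataclass(frozen=True)
class InjectionSchedule:
    """Titration geometry: cell volume and concentrations plus injections.

    Parameters
    ----------
    cell_volume:
        Active cell volume V0 in liters.
    cell_conc0:
        Initial macromolecule concentration in the cell, molar.
    syringe_conc:
        Titrant concentration in the syringe, molar.
    injection_volumes:
        Ordered per-injection volumes in liters (at least 2 injections).
    temperature:
        Kelvin.
    """

    cell_volume: float
    cell_conc0: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = T_DEFAULT

    def __post_init__(self):
        object.__setattr__(self, "injection_volumes", tuple(self.injection_volumes))
        if not (self.cell_volume > 0 and self.cell_conc0 > 0 and self.syringe_conc > 0):
            raise ScheduleError("volumes and concentrations must be strictly positive")
        if len(self.injection_volumes) < 2:
            raise ScheduleError("a titration needs at least 2 injections")
        if any(dv <= 0 for dv in self.injection_volumes):
            raise ScheduleError("injection volumes must be strictly positive")
        if sum(self.injection_volumes) >= 2 * self.cell_volume:
            raise ScheduleError(
                "cumulative injected volume must stay below twice the cell volume"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @property
    def cumulative_volumes(self) -> np.ndarray:
        """Cumulative injected volume after each injection, liters."""
        return np.cumsum(self.injection_volumes)

    @property
    def final_molar_ratio(self) -> float:
        """Total injected titrant moles over initial cell macromolecule moles."""
        v = float(np.sum(self.injection_volumes))
        return (v * self.syringe_conc) / (self.cell_volume * self.cell_conc0)

    def to_dict(self) -> dict:
        return {
            "cell_volume_L": self.cell_volume,
            "cell_conc_M": self.cell_conc0,
            "syringe_conc_M": self.syringe_conc,
            "injection_volumes_L": list(self.injection_volumes),
            "temperature_K": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InjectionSchedule":
        return cls(
            cell_volume=float(d["cell_volume_L"]),
            cell_conc0=float(d["cell_conc_M"]),
            syringe_conc=float(d["syringe_conc_M"]),
            injection_volumes=tuple(float(v) for v in d["injection_volumes_L"]),
            temperature=float(d.get("temperature_K", T_DEFAULT)),
        )


@dataclass(frozen=True)
class Isotherm:
    """One titration's integrated heats.

    ``raw_heats`` are per-injection heats in ucal, ``normalized_heats`` the
    same heats per mole of injectant in kcal/mol, and ``molar_ratios`` the
    cumulative titrant:macromolecule ratio after each injection.
    """

    schedule: InjectionSchedule
    raw_heats: np.ndarray
    normalized_heats: np.ndarray
    molar_ratios: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name in ("raw_heats", "normalized_heats", "molar_ratios"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.schedule.n_injections
        for name in ("raw_heats", "normalized_heats", "molar_ratios"):
            if len(getattr(self, name)) != n:
                raise DomainError(f"{name} must have one entry per injection ({n})")
        if np.any(np.diff(self.molar_ratios) <= 0):
            raise DomainError("molar ratios must be strictly increasing")

    @property
    def n_injections(self) -> int:
        return self.schedule.n_injections


@dataclass(frozen=True)
class SequentialModel:
    """Ordered three-event sequential binding model on the hexamer basis.

    ``ka = (k1, k2, k3)`` are stepwise association constants in 1/molar and
    ``dh = (h1, h2, h3)`` the corresponding event enthalpies in kcal/mol.
    Events 1-2 are the intratrimer LC8 additions, event 3 the bridging one.
    ``macromolecule_basis`` records which unit the cell concentration counts;
    the hexamer basis equals the trimer concentration divided by two.
    """

    ka: tuple[float, float, float]
    dh: tuple[float, float, float]
    macromolecule_basis: str = "hexamer"

    def __post_init__(self):
        object.__setattr__(self, "ka", tuple(float(k) for k in self.ka))
        object.__setattr__(self, "dh", tuple(float(h) for h in self.dh))
        if len(self.ka) != 3 or len(self.dh) != 3:
            raise DomainError("sequential model has exactly 3 events")
        if any(k < 0 for k in self.ka):
            raise DomainError("association constants must be non-negative")

    @property
    def betas(self) -> np.ndarray:
        """Cumulative products beta_j = k1*...*kj for j = 1..3."""
        return np.cumprod(self.ka)

    @property
    def cumulative_dh(self) -> np.ndarray:
        """H_j = h1 + ... + hj for j = 1..3, kcal/mol."""
        return np.cumsum(self.dh)


def dilute_concentrations(schedule: InjectionSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Total cell-species and titrant concentrations after each injection.

    Uses the symmetric half-volume perfusion convention: after cumulative
    injected volume v,

        M_t = M0 * (1 - v/(2 V0)) / (1 + v/(2 V0))
        X_t = Xs * (v / V0)       / (1 + v/(2 V0))

    Returns (macromolecule_total, titrant_total) arrays in molar.
    """
    v = schedule.cumulative_volumes
    v0 = schedule.cell_volume
    if v[-1] >= 2 * v0:
        raise ScheduleError("cumulative injected volume reached twice the cell volume")
    half = v / (2 * v0)
    m_total = schedule.cell_conc0 * (1 - half) / (1 + half)
    x_total = schedule.syringe_conc * (v / v0) / (1 + half)
    return m_total, x_total


def oss_total_heat(
    params: ThermoParams,
    m_total: np.ndarray | float,
    x_total: np.ndarray | float,
    cell_volume: float,
) -> np.ndarray | float:
    """Closed-form one-set-of-sites total heat content Q in kcal.

    Wiseman closed form: with r = X_t/(n M_t) and s = 1/(n Ka M_t),

        Q = (n M_t dH V0 / 2) * [1 + r + s - sqrt((1 + r + s)^2 - 4 r)]

    Q carries the sign of dH and the amount bound never exceeds
    min(X_t, n M_t).
    """
    m = np.asarray(m_total, dtype=float)
    x = np.asarray(x_total, dtype=float)
    if np.any(m < 0) or np.any(x < 0):
        raise DomainError("concentrations must be non-negative")
    n, ka, dh = params.n_sites, params.ka, params.dh
    out = np.zeros(np.broadcast(m, x).shape)
    nz = m > 0
    mnz = np.where(nz, m, 1.0)
    r = x / (n * mnz)
    s = 1.0 / (n * ka * mnz)
    c1 = 1.0 + r + s
    disc = c1 * c1 - 4.0 * r
    if np.any(disc < 0):
        raise SolverError(
            "negative discriminant in OSS closed form", c1=c1, r=r, s=s
        )
    q = (n * mnz * dh * cell_volume / 2.0) * (c1 - np.sqrt(disc))
    out = np.where(nz, q, 0.0)
    if np.isscalar(m_total) and np.isscalar(x_total):
        return float(out)
    return out


def heats_from_totals(
    q_totals: np.ndarray,
    schedule: InjectionSchedule,
    displacement_correction: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-injection raw (ucal) and normalized (kcal/mol) heats from Q(i).

    ``q_totals`` is the total heat content (kcal) after each injection,
    with Q = 0 before the first.
    """
    q = np.concatenate([[0.0], np.asarray(q_totals, dtype=float)])
    dv = np.asarray(schedule.injection_volumes)
    dq = np.diff(q)
    if displacement_correction:
        dq = dq + (dv / schedule.cell_volume) * (q[1:] + q[:-1]) / 2.0
    raw_ucal = dq * UCAL_PER_KCAL
    normalized = dq / (dv * schedule.syringe_conc)
    return raw_ucal, normalized


def oss_isotherm(
    params: ThermoParams,
    schedule: InjectionSchedule,
    displacement_correction: bool = True,
) -> Isotherm:
    """Simulate a noiseless one-set-of-sites titration."""
    m_total, x_total = dilute_concentrations(schedule)
    q = oss_total_heat(params, m_total, x_total, schedule.cell_volume)
    raw, norm = heats_from_totals(q, schedule, displacement_correction)
    return Isotherm(
        schedule=schedule,
        raw_heats=raw,
        normalized_heats=norm,
        molar_ratios=x_total / m_total,
        meta={"model": "oss"},
    )


def sequential_fractions(model: SequentialModel, free_ligand: float) -> np.ndarray:
    """Populations (F_0..F_3) of the 0-, 1-, 2-, 3-bound macromolecule states.

    F_j = beta_j L^j / sum_j beta_j L^j with beta_0 = 1; sums to 1.
    """
    if free_ligand < 0:
        raise DomainError("free ligand concentration must be non-negative")
    betas = np.concatenate([[1.0], model.betas])
    terms = betas * free_ligand ** np.arange(4)
    return terms / terms.sum()


def sequential_free_ligand(
    model: SequentialModel, m_total: float, x_total: float
) -> float:
    """Free titrant concentration L solving the sequential mass balance.

    Solves ``x_total = L + m_total * sum_j j F_j(L)`` by bracketed Brent
    iteration on [0, x_total]; the residual at return is below
    1e-12 * x_total.
    """
    if m_total < 0 or x_total < 0:
        raise DomainError("totals must be non-negative")
    if x_total == 0:
        return 0.0

    def residual(ell: float) -> float:
        f = sequential_fractions(model, ell)
        bound = m_total * (f[1] + 2 * f[2] + 3 * f[3])
        return ell + bound - x_total

    if residual(x_total) <= 0:  # no binding (all ka == 0)
        return x_total
    ell = brentq(residual, 0.0, x_total, xtol=1e-30, rtol=4 * np.finfo(float).eps,
                 maxiter=200)
    res = residual(ell)
    if abs(res) > 1e-12 * x_total:
        raise SolverError(
            "sequential mass balance did not converge",
            residual=res, bracket=(0.0, x_total), free_ligand=ell,
        )
    return float(ell)


def sequential_total_heat(
    model: SequentialModel,
    m_total: np.ndarray,
    x_total: np.ndarray,
    cell_volume: float,
) -> np.ndarray:
    """Total heat content Q (kcal) of the sequential model at given totals."""
    m = np.atleast_1d(np.asarray(m_total, dtype=float))
    x = np.atleast_1d(np.asarray(x_total, dtype=float))
    h_cum = model.cumulative_dh
    q = np.empty_like(m)
    for i in range(len(m)):
        ell = sequential_free_ligand(model, m[i], x[i])
        f = sequential_fractions(model, ell)
        q[i] = m[i] * cell_volume * float(np.dot(f[1:], h_cum))
    return q


def sequential_isotherm(
    model: SequentialModel,
    schedule: InjectionSchedule,
    displacement_correction: bool = True,
    reverse_roles: bool = False,
) -> Isotherm:
    """Simulate a sequential-model titration.

    With ``reverse_roles=False`` the macromolecule (hexamer basis) sits in
    the cell and the ligand in the syringe.  With ``reverse_roles=True`` the
    roles are swapped (ligand in the cell, macromolecule titrated in), the
    configuration used to test for titration-order-dependent intermediates.
    Molar ratios are always reported as titrant:cell species.
    """
    cell_total, syringe_total = dilute_concentrations(schedule)
    if reverse_roles:
        m_total, x_total = syringe_total, cell_total
    else:
        m_total, x_total = cell_total, syringe_total
    q = sequential_total_heat(model, m_total, x_total, schedule.cell_volume)
    raw, norm = heats_from_totals(q, schedule, displacement_correction)
    return Isotherm(
        schedule=schedule,
        raw_heats=raw,
        normalized_heats=norm,
        molar_ratios=syringe_total / cell_total,
        meta={"model": "sequential", "reverse_roles": reverse_roles},
    )


def count_phases(normalized_heats: np.ndarray, rel_tol: float = 0.02) -> int:
    """Number of transition phases in a normalized-heat curve.

    Counts sign changes of the second difference of the curve, ignoring
    changes smaller than ``rel_tol`` times the curve's amplitude.  A
    single-phase sigmoidal isotherm has one dominant inflection (1 sign
    change); a two-phase curve with a visible intermediate has >= 2.
    """
    h = np.asarray(normalized_heats, dtype=float)
    d2 = np.diff(h, n=2)
    scale = np.max(h) - np.min(h)
    if scale == 0:
        return 0
    keep = d2[np.abs(d2) > rel_tol * scale]
    if len(keep) == 0:
        return 0
    return int(np.sum(np.diff(np.sign(keep)) != 0))
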