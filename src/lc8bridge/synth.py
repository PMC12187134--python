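"""Synthetic ITC titrations with known ground truth.

Emulates VP-ITC titrations of the modeled experiments: titrant at
250-400 uM in the syringe, macromolecule at 10-35 uM in the cell, 28
injections of 10 uL into a 1.4 mL cell at 25 degC (injection count and
volumes are package conventions).  Gaussian
noise is applied to the raw per-injection heats in ucal — instrument noise
is per injection, and normalization rescales it by the injected moles.

Determinism: a single integer master seed; replicate r uses sub-seed
``seed + r`` via :func:`numpy.random.default_rng`.

Presets named after the constructs carry each construct's measured
one-set-of-sites parameters (N, Kd, dH) and, for the QT2 variant, the
sequential intratrimer/bridging affinity pair (0.3 uM / 1.1 uM); sequential
preset enthalpies are package test choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError
from .forward import (
    InjectionSchedule,
    Isotherm,
    SequentialModel,
    dilute_concentrations,
    oss_isotherm,
    sequential_isotherm,
)
from .thermo import T_DEFAULT, ThermoParams

#: Default VP-ITC-like schedule conventions.
DEFAULT_N_INJECTIONS = 28
DEFAULT_INJECTION_VOLUME_L = 10e-6
DEFAULT_CELL_VOLUME_L = 1.4e-3
#: Default per-injection heat noise, ucal.
DEFAULT_NOISE_UCAL = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic titration (model + schedule + noise + seed)."""

    generating_model: ThermoParams | SequentialModel
    schedule: InjectionSchedule
    noise_sigma: float = DEFAULT_NOISE_UCAL
    n_replicates: int = 1
    seed: int = 0
    reverse_roles: bool = False

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")


def make_schedule(
    cell_conc: float,
    syringe_conc: float,
    n_injections: int = DEFAULT_N_INJECTIONS,
    injection_volume: float = DEFAULT_INJECTION_VOLUME_L,
    cell_volume: float = DEFAULT_CELL_VOLUME_L,
    temperature: float = T_DEFAULT,
) -> InjectionSchedule:
    """Uniform-volume injection schedule.

    The final molar ratio reached is
    ``n_injections * injection_volume * syringe_conc /
    (cell_volume * cell_conc)``.
    """
    if n_injections < 2:
        raise DomainError("need at least 2 injections")
    return InjectionSchedule(
        cell_volume=cell_volume,
        cell_conc0=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=temperature,
    )


def _noiseless(spec: SyntheticSpec) -> Isotherm:
    if isinstance(spec.generating_model, ThermoParams):
        if spec.reverse_roles:
            raise ConfigError("reverse_roles applies to the sequential model only")
        return oss_isotherm(spec.generating_model, spec.schedule)
    return sequential_isotherm(
        spec.generating_model, spec.schedule, reverse_roles=spec.reverse_roles
    )


def gen_isotherm(spec: SyntheticSpec, seed: int | None = None) -> Isotherm:
    """One noisy synthetic isotherm; deterministic for a fixed seed.

    Noise is i.i.d. Gaussian with sd ``noise_sigma`` on the raw ucal heats;
    normalized heats are recomputed from the noisy raw heats.  The ground
    truth (generating parameters, seed, sigma) is embedded in ``meta``.
    """
    seed = spec.seed if seed is None else seed
    base = _noiseless(spec)
    rng = np.random.default_rng(seed)
    raw = base.raw_heats + rng.normal(0.0, spec.noise_sigma, base.n_injections)
    dv = np.asarray(spec.schedule.injection_volumes)
    norm = (raw * 1e-9) / (dv * spec.schedule.syringe_conc)
    model = spec.generating_model
    truth = {
        "seed": seed,
        "noise_sigma_ucal": spec.noise_sigma,
        "model": "oss" if isinstance(model, ThermoParams) else "sequential",
    }
    if isinstance(model, ThermoParams):
        truth.update(n=model.n_sites, kd_M=model.kd, dh_kcal_mol=model.dh)
    else:
        truth.update(ka_per_M=list(model.ka), dh_kcal_mol=list(model.dh))
    return Isotherm(
        schedule=base.schedule,
        raw_heats=raw,
        normalized_heats=norm,
        molar_ratios=base.molar_ratios,
        meta={**base.meta, "ground_truth": truth},
    )


def gen_replicates(spec: SyntheticSpec) -> list[Isotherm]:
    """``n_replicates`` isotherms with sub-seeds seed, seed+1, ...

    All replicates share the noiseless backbone and ground truth.
    """
    return [gen_isotherm(spec, seed=spec.seed + r) for r in range(spec.n_replicates)]


# --- presets -----------------------------------------------------------------

#: One-set-of-sites parameters (N, Kd uM, dH kcal/mol) per construct.
OSS_PRESETS: dict[str, ThermoParams] = {
    "wt-lbd-od": ThermoParams(n_sites=2.8, kd=0.4e-6, dh=-9.7),
    "qt1-od": ThermoParams(n_sites=1.1, kd=5.0e-6, dh=-7.1),
    "qt2-od": ThermoParams(n_sites=1.2, kd=1.2e-6, dh=-10.6),
    "qt3-od": ThermoParams(n_sites=0.87, kd=0.86e-6, dh=-6.9),
    "qt12-od": ThermoParams(n_sites=2.3, kd=0.5e-6, dh=-9.4),
    "qt13-od": ThermoParams(n_sites=2.1, kd=0.7e-6, dh=-5.6),
    "qt23-od": ThermoParams(n_sites=1.9, kd=0.4e-6, dh=-7.0),
}

#: Sequential (hexamer-basis) presets.  The QT2 affinity pair is the fitted
#: intratrimer 0.3 uM / bridging 1.1 uM; enthalpies are package choices.
SEQUENTIAL_PRESETS: dict[str, SequentialModel] = {
    "qt2-od-sbs": SequentialModel(
        ka=(1 / 0.3e-6, 1 / 0.3e-6, 1 / 1.1e-6), dh=(-10.0, -10.0, -5.0)
    ),
    # weak, well-separated bridging event: produces the two-phase isotherm
    "qt3-od-sbs": SequentialModel(
        ka=(1 / 0.6e-6, 1 / 0.6e-6, 1 / 5.0e-6), dh=(-10.0, -10.0, -3.0)
    ),
}


def preset_spec(
    name: str,
    cell_conc: float = 20e-6,
    syringe_conc: float = 300e-6,
    noise_sigma: float = DEFAULT_NOISE_UCAL,
    n_replicates: int = 3,
    seed: int = 0,
    **schedule_kwargs,
) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a named construct preset.

    Sequential presets default the cell concentration to the hexamer basis
    (10 uM for a 20 uM trimer cell).
    """
    if name in OSS_PRESETS:
        model = OSS_PRESETS[name]
    elif name in SEQUENTIAL_PRESETS:
        model = SEQUENTIAL_PRESETS[name]
    else:
        raise ConfigError(
            f"unknown preset {name!r}; known: "
            + ", ".join(sorted(OSS_PRESETS) + sorted(SEQUENTIAL_PRESETS))
        )
    schedule = make_schedule(cell_conc, syringe_conc, **schedule_kwargs)
    return SyntheticSpec(
        generating_model=model,
        schedule=schedule,
        noise_sigma=noise_sigma,
        n_replicates=n_replicates,
        seed=seed,
    )
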