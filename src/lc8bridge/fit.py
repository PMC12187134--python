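"""Inverse problem: fit binding models to isotherms and aggregate replicates.

Two fitters are provided.  ``fit_oss`` estimates (N, Ka, dH) of the
one-set-of-sites model; ``fit_sequential_constrained`` estimates the
three-event sequential model under the constraint set used for the
53BP1 hexamer analysis: the two intratrimer events share a constant and an
enthalpy (k1 = k2, h1 = h2) and the bridging event is weaker but more
enthalpically favorable is *not* assumed — only the ordering k1 > k3 and
h1 < h3 is enforced, by smooth reparametrization

    k3 = k1 * exp(-delta^2),    h3 = h1 + eps^2

with delta and eps free, which keeps the problem differentiable and makes
every iterate feasible.  Association constants are optimized as log values
since they span decades.

Replicate estimates are combined by inverse-variance weighting:
y_hat = sum(y_i/s_i^2)/sum(1/s_i^2) with aggregate error 1/sum(1/s_i^2)
(deliberately kept on this variance scale as the package's canonical
aggregation rule); ``conventional=True`` returns its square root instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, DomainError, SolverError
from .forward import (
    Isotherm,
    SequentialModel,
    dilute_concentrations,
    heats_from_totals,
    oss_total_heat,
    sequential_total_heat,
)
from .thermo import DerivedThermo, ThermoParams, delta_g_from_kd, neg_t_delta_s


@dataclass(frozen=True)
class ConstraintSpec:
    """Equality groups and strict-order constraints on sequential parameters.

    ``equalities`` are groups of parameter names forced equal;
    ``inequalities`` are ordered (greater, lesser) pairs.  The canonical set
    for the hexamer model is ``{k1,k2}``, ``{h1,h2}`` with k1 > k3 and
    h3 > h1.
    """

    equalities: tuple[frozenset, ...] = (frozenset({"k1", "k2"}), frozenset({"h1", "h2"}))
    inequalities: tuple[tuple[str, str], ...] = (("k1", "k3"), ("h3", "h1"))

    _PARAMS = frozenset({"k1", "k2", "k3", "h1", "h2", "h3"})

    def __post_init__(self):
        object.__setattr__(
            self, "equalities", tuple(frozenset(g) for g in self.equalities)
        )
        object.__setattr__(
            self, "inequalities", tuple(tuple(p) for p in self.inequalities)
        )
        seen = set()
        for group in self.equalities:
            if not group <= self._PARAMS:
                raise ConfigError(f"unknown parameters in equality group {set(group)}")
            if seen & group:
                raise ConfigError("a parameter appears in two equality groups")
            seen |= group
        for hi, lo in self.inequalities:
            if hi not in self._PARAMS or lo not in self._PARAMS:
                raise ConfigError(f"inequality references unknown parameter ({hi},{lo})")


def default_sequential_constraints() -> ConstraintSpec:
    """The constraint set of the hexamer bridging analysis."""
    return ConstraintSpec()


@dataclass
class FitResult:
    """Fitted parameters with standard errors and derived thermodynamics.

    ``params``/``std_errors`` are name->value dicts (``n``, ``kd``, ``dh``,
    and optionally ``offset`` for the OSS model; ``k1``..``h3`` plus derived
    ``kd_intra``/``kd_bridge`` for the sequential model).  ``derived`` maps
    event names to :class:`DerivedThermo`.
    """

    model: str
    params: dict
    std_errors: dict
    residual_rms: float
    converged: bool
    n_iterations: int
    ill_conditioned: bool = False
    derived: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None
    temperature: float | None = None


def aggregate_inverse_variance(
    values, sigmas, conventional: bool = False
) -> tuple[float, float]:
    """Inverse-variance weighted aggregate of replicate measurements.

    Returns ``(y_hat, sigma_hat)`` with ``y_hat = sum(y/s^2)/sum(1/s^2)``
    and ``sigma_hat = 1/sum(1/s^2)`` (note this aggregate error is a
    variance-scale quantity).  With ``conventional=True`` the square root —
    the standard error of the weighted mean — is returned.
    """
    y = np.asarray(values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if y.size == 0 or y.shape != s.shape:
        raise DomainError("values and sigmas must be equal-length and non-empty")
    if np.any(s <= 0):
        raise DomainError("all sigmas must be strictly positive")
    w = 1.0 / s**2
    y_hat = float(np.sum(w * y) / np.sum(w))
    var_scale = float(1.0 / np.sum(w))
    return y_hat, math.sqrt(var_scale) if conventional else var_scale


def _std_errors_from_jacobian(jac: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """Per-parameter standard errors from the Jacobian at the optimum."""
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0, np.inf)), cov
    except np.linalg.LinAlgError:
        return np.full(p, np.inf), np.full((p, p), np.inf)


def _initial_oss_guess(isotherm: Isotherm) -> tuple[float, float, float]:
    """Heuristic (n, Ka, dH) start from isotherm shape.

    dH from the first-injection plateau, n from the molar-ratio position of
    the steepest heat change, Ka from the width of the transition.
    """
    r = isotherm.molar_ratios
    h = isotherm.normalized_heats
    dh0 = float(h[0])
    steps = np.abs(np.diff(h))
    i_star = int(np.argmax(steps))
    n0 = float(np.clip((r[i_star] + r[i_star + 1]) / 2.0, 0.05, r[-1]))
    # transition width in molar-ratio units ~ 4/sqrt(c) around r = n
    width = max(float(r[min(i_star + 2, len(r) - 1)] - r[max(i_star - 2, 0)]), 1e-2)
    c0 = float(np.clip((4.0 / width) ** 2, 1.0, 1e4))
    ka0 = c0 / (n0 * isotherm.schedule.cell_conc0)
    return n0, ka0, dh0 if dh0 != 0 else -1.0


def fit_oss(
    isotherm: Isotherm,
    init: ThermoParams | None = None,
    fit_offset: bool = False,
    exclude_first: bool = False,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the one-set-of-sites model to normalized heats.

    Parameters are (n, ln Ka, dH) plus an optional constant per-injection
    dilution offset.  Standard errors come from the Jacobian at the optimum;
    a flat isotherm is returned flagged ill-conditioned instead of producing
    a spurious affinity.
    """
    if isotherm.n_injections < 5:
        raise DomainError("need at least 5 injections to fit")
    sched = isotherm.schedule
    m_total, x_total = dilute_concentrations(sched)
    h_obs = isotherm.normalized_heats
    mask = np.ones(len(h_obs), dtype=bool)
    if exclude_first:
        mask[0] = False

    if np.max(np.abs(h_obs)) < 1e-9:
        return FitResult(
            model="oss",
            params={"n": np.nan, "kd": np.nan, "dh": np.nan},
            std_errors={"n": np.nan, "kd": np.nan, "dh": np.nan},
            residual_rms=0.0,
            converged=False,
            n_iterations=0,
            ill_conditioned=True,
            temperature=sched.temperature,
        )

    def model_heats(theta):
        n, ln_ka, dh = theta[:3]
        params = ThermoParams(
            n_sites=n, kd=math.exp(-ln_ka), dh=dh, temperature=sched.temperature
        )
        q = oss_total_heat(params, m_total, x_total, sched.cell_volume)
        _, norm = heats_from_totals(q, sched)
        if fit_offset:
            norm = norm + theta[3]
        return norm

    def residual(theta):
        return model_heats(theta)[mask] - h_obs[mask]

    if init is not None:
        starts = [(init.n_sites, math.log(init.ka), init.dh)]
    else:
        n0, ka0, dh0 = _initial_oss_guess(isotherm)
        starts = [(n0, math.log(ka0), dh0)]
        # log-spaced Ka multi-start guards against a poor width estimate
        starts += [(n0, math.log(10.0**e), dh0) for e in (4, 5, 6, 7)]

    best = None
    for n0, lka0, dh0 in starts:
        theta0 = [n0, lka0, dh0] + ([0.0] if fit_offset else [])
        lower = [1e-3, math.log(1e-1), -np.inf] + ([-np.inf] if fit_offset else [])
        upper = [50.0, math.log(1e15), np.inf] + ([np.inf] if fit_offset else [])
        try:
            res = least_squares(
                residual, theta0, bounds=(lower, upper), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except (ValueError, SolverError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise SolverError("OSS fit failed from every start", starts=starts)

    errs, cov = _std_errors_from_jacobian(best.jac, best.fun)
    n_fit, ln_ka_fit, dh_fit = best.x[:3]
    kd_fit = math.exp(-ln_ka_fit)
    params = {"n": float(n_fit), "kd": kd_fit, "dh": float(dh_fit)}
    # sigma(kd) = kd * sigma(ln Ka) to first order
    std = {"n": float(errs[0]), "kd": kd_fit * float(errs[1]), "dh": float(errs[2])}
    if fit_offset:
        params["offset"] = float(best.x[3])
        std["offset"] = float(errs[3])
    result = FitResult(
        model="oss",
        params=params,
        std_errors=std,
        residual_rms=float(np.sqrt(np.mean(best.fun**2))),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
        residuals=best.fun,
        temperature=sched.temperature,
    )
    return derive_thermo(result, sched.temperature)


def _sequential_from_theta(theta, fit_offset):
    """Map free vector (ln k1, delta, h1, eps[, offset]) to a feasible model."""
    ln_k1, delta, h1, eps = theta[:4]
    k1 = math.exp(ln_k1)
    k3 = k1 * math.exp(-(delta**2))
    h3 = h1 + eps**2
    offset = theta[4] if fit_offset else 0.0
    return SequentialModel(ka=(k1, k1, k3), dh=(h1, h1, h3)), offset


def fit_sequential_constrained(
    isotherm: Isotherm,
    constraints: ConstraintSpec | None = None,
    init: SequentialModel | None = None,
    fit_offset: bool = False,
    exclude_first: bool = False,
    seed: int = 0,
    n_starts: int = 5,
) -> FitResult:
    """Constrained three-event sequential fit (k1=k2, h1=h2, k1>k3, h1<h3).

    Equalities are enforced by parameter sharing and the strict orderings by
    the smooth reparametrization ``k3 = k1 exp(-delta^2)``,
    ``h3 = h1 + eps^2``, so returned values always satisfy the constraints.
    Five jittered multi-starts (sub-seeded from ``seed``) guard against
    local minima; an infeasible ``init`` is projected into the feasible
    region before optimization.
    """
    constraints = constraints if constraints is not None else ConstraintSpec()
    canonical = ConstraintSpec()
    if (
        set(constraints.equalities) != set(canonical.equalities)
        or set(constraints.inequalities) != set(canonical.inequalities)
    ):
        raise ConfigError(
            "only the hexamer constraint structure (k1=k2, h1=h2, k1>k3, h1<h3) "
            "is supported"
        )
    if isotherm.n_injections < 5:
        raise DomainError("need at least 5 injections to fit")
    sched = isotherm.schedule
    m_total, x_total = dilute_concentrations(sched)
    h_obs = isotherm.normalized_heats
    mask = np.ones(len(h_obs), dtype=bool)
    if exclude_first:
        mask[0] = False

    def residual(theta):
        model, offset = _sequential_from_theta(theta, fit_offset)
        q = sequential_total_heat(model, m_total, x_total, sched.cell_volume)
        _, norm = heats_from_totals(q, sched)
        return (norm + offset)[mask] - h_obs[mask]

    if init is not None:
        k1 = max(init.ka[0], init.ka[1], 1e-6)
        k3 = min(init.ka[2], k1 * (1 - 1e-9)) if init.ka[2] > 0 else k1 * 0.1
        h1 = min(init.dh[0], init.dh[1])
        h3 = max(init.dh[2], h1)
        theta0 = np.array(
            [math.log(k1), math.sqrt(max(math.log(k1 / k3), 1e-12)), h1,
             math.sqrt(max(h3 - h1, 1e-12))]
        )
    else:
        dh0 = float(h_obs[0]) or -1.0
        # per-event start: half the apparent plateau, affinity ~ 1 uM
        theta0 = np.array([math.log(1e6), 1.0, dh0 / 2.0, 1.0])
    if fit_offset:
        theta0 = np.append(theta0, 0.0)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        jitter = np.zeros_like(theta0)
        if start > 0:
            jitter[:4] = rng.normal(0, [1.0, 0.5, abs(theta0[2]) * 0.3 + 0.1, 0.5])
        try:
            res = least_squares(
                residual, theta0 + jitter, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except (ValueError, SolverError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise SolverError("sequential fit failed from every start")

    errs, cov = _std_errors_from_jacobian(best.jac, best.fun)
    model, offset = _sequential_from_theta(best.x, fit_offset)
    k1, _, k3 = model.ka
    h1, _, h3 = model.dh
    # first-order error propagation through the reparametrization
    ln_k1, delta, _, eps = best.x[:4]
    s_lnk1, s_delta, s_h1, s_eps = errs[:4]
    s_k1 = k1 * s_lnk1
    s_lnk3 = math.hypot(s_lnk1, 2 * abs(delta) * s_delta)
    s_k3 = k3 * s_lnk3
    s_h3 = math.hypot(s_h1, 2 * abs(eps) * s_eps)
    params = {
        "k1": k1, "k2": k1, "k3": k3,
        "h1": h1, "h2": h1, "h3": h3,
        "kd_intra": 1.0 / k1, "kd_bridge": 1.0 / k3,
    }
    std = {
        "k1": s_k1, "k2": s_k1, "k3": s_k3,
        "h1": s_h1, "h2": s_h1, "h3": s_h3,
        "kd_intra": s_k1 / k1**2, "kd_bridge": s_k3 / k3**2,
    }
    if fit_offset:
        params["offset"] = float(offset)
        std["offset"] = float(errs[4])
    # flag fits whose event parameters are undetermined: affinities uncertain
    # beyond a factor e, or a bridging enthalpy error swamping the h3-h1 gap
    ill = (
        not (np.isfinite(s_lnk1) and np.isfinite(s_lnk3) and np.isfinite(s_h3))
        or s_lnk1 > 1.0
        or s_lnk3 > 1.0
        or s_h3 > max(1.0, abs(h3 - h1))
    )
    result = FitResult(
        model="sequential",
        params=params,
        std_errors=std,
        residual_rms=float(np.sqrt(np.mean(best.fun**2))),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
        ill_conditioned=bool(ill),
        residuals=best.fun,
        temperature=sched.temperature,
    )
    return derive_thermo(result, sched.temperature)


def derive_thermo(fit: FitResult, temperature: float | None = None) -> FitResult:
    """Attach per-event dG and -T dS (with propagated errors) to a fit.

    For each (kd, dh) pair carried by the fit: ``dg = R T ln(kd)``,
    ``-T dS = dg - dh``; errors are propagated to first order
    (``s_dg = R T s_kd / kd``, ``s_(-TdS) = sqrt(s_dg^2 + s_dh^2)``).
    """
    temperature = temperature if temperature is not None else (fit.temperature or 298.15)
    pairs = {}
    if fit.model == "oss":
        if np.isfinite(fit.params.get("kd", np.nan)):
            pairs["site"] = ("kd", "dh")
    elif fit.model == "sequential":
        pairs["intratrimer"] = ("kd_intra", "h1")
        pairs["bridging"] = ("kd_bridge", "h3")
    derived = {}
    from .thermo import R_KCAL

    for name, (kd_key, dh_key) in pairs.items():
        kd = fit.params[kd_key]
        dh = fit.params[dh_key]
        s_kd = fit.std_errors.get(kd_key, 0.0)
        s_dh = fit.std_errors.get(dh_key, 0.0)
        dg = delta_g_from_kd(kd, temperature)
        s_dg = R_KCAL * temperature * (s_kd / kd) if np.isfinite(s_kd) else np.inf
        nts = neg_t_delta_s(dg, dh)
        s_nts = math.hypot(s_dg, s_dh) if np.isfinite(s_dg) and np.isfinite(s_dh) else np.inf
        derived[name] = DerivedThermo(dg=dg, neg_t_ds=nts, dg_err=s_dg, neg_t_ds_err=s_nts)
    fit.derived = derived
    fit.temperature = temperature
    return fit
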