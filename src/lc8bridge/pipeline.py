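"""End-to-end pipeline: simulate -> fit -> aggregate (-> speciate).

``run_pipeline`` takes a plain-dict configuration (typically loaded from
YAML), executes the requested chain, and returns a structured report that
embeds the exact configuration used, package version, per-stage logs and
seeds.  Rerunning with an identical configuration reproduces the report
byte-for-byte apart from the timestamp field.
"""

from __future__ import annotations

import datetime
import logging
import math
import time

from .errors import ConfigError
from .fit import (
    FitResult,
    aggregate_inverse_variance,
    default_sequential_constraints,
    fit_oss,
    fit_sequential_constrained,
)
from .speciation import LadderModel, mass_profile, speciate
from .synth import SyntheticSpec, gen_replicates, make_schedule, preset_spec
from .thermo import MassTable

logger = logging.getLogger("lc8bridge")

__version__ = "0.1.0"


def _fit_one(isotherm, model: str, seed: int, exclude_first: bool) -> FitResult:
    if model == "oss":
        return fit_oss(isotherm, exclude_first=exclude_first, seed=seed)
    if model == "sequential":
        return fit_sequential_constrained(
            isotherm,
            constraints=default_sequential_constraints(),
            exclude_first=exclude_first,
            seed=seed,
        )
    raise ConfigError(f"unknown model {model!r} (expected 'oss' or 'sequential')")


def _fit_summary(fit: FitResult) -> dict:
    out = {
        "model": fit.model,
        "params": {k: float(v) for k, v in fit.params.items()},
        "std_errors": {k: float(v) for k, v in fit.std_errors.items()},
        "residual_rms_kcal_mol": fit.residual_rms,
        "converged": fit.converged,
        "ill_conditioned": fit.ill_conditioned,
        "derived": {
            name: {
                "dG_kcal_mol": d.dg,
                "neg_TdS_kcal_mol": d.neg_t_ds,
                "dG_err": d.dg_err,
                "neg_TdS_err": d.neg_t_ds_err,
            }
            for name, d in fit.derived.items()
        },
    }
    return out


def _aggregate(fits: list[FitResult], keys: list[str]) -> dict:
    """Inverse-variance aggregate of selected parameters across replicate fits."""
    agg = {}
    for key in keys:
        vals = [f.params[key] for f in fits if math.isfinite(f.params.get(key, math.nan))]
        sigs = [f.std_errors[key] for f in fits if math.isfinite(f.params.get(key, math.nan))]
        if not vals or any(not (s > 0) or not math.isfinite(s) for s in sigs):
            continue
        y_hat, s_hat = aggregate_inverse_variance(vals, sigs)
        agg[key] = {"value": y_hat, "error": s_hat, "n_replicates": len(vals)}
    # derived thermodynamics are aggregated after per-replicate derivation
    for event in fits[0].derived:
        for attr, err_attr, label in (
            ("dg", "dg_err", "dG_kcal_mol"),
            ("neg_t_ds", "neg_t_ds_err", "neg_TdS_kcal_mol"),
        ):
            vals = [getattr(f.derived[event], attr) for f in fits if event in f.derived]
            sigs = [getattr(f.derived[event], err_attr) for f in fits if event in f.derived]
            if vals and all(s > 0 and math.isfinite(s) for s in sigs):
                y_hat, s_hat = aggregate_inverse_variance(vals, sigs)
                agg[f"{event}.{label}"] = {
                    "value": y_hat, "error": s_hat, "n_replicates": len(vals)
                }
    return agg


def run_pipeline(config: dict) -> dict:
    """Execute a simulate->fit->aggregate (optionally ->speciate) chain.

    Configuration keys: ``preset`` (or explicit ``schedule``/model params),
    ``model`` ('oss'|'sequential'), ``n_replicates``, ``noise_sigma_ucal``,
    ``seed``, ``exclude_first``, optional ``speciation`` block
    (``q``, ``kd_intra_M``, ``kd_bridge_M``, ``total_trimer_M``,
    ``total_lc8_M``, ``degeneracy``) and optional ``mass_table`` overrides.
    """
    if "preset" not in config:
        raise ConfigError("pipeline config requires a 'preset'")
    model_kind = config.get("model", "oss")
    if model_kind not in ("oss", "sequential"):
        raise ConfigError(f"unknown model {model_kind!r}")
    seed = int(config.get("seed", 0))
    stages = []
    report: dict = {
        "package": "lc8bridge",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "stages": stages,
    }

    t0 = time.perf_counter()
    spec = preset_spec(
        config["preset"],
        cell_conc=float(config.get("cell_conc_M", 20e-6 if model_kind == "oss" else 10e-6)),
        syringe_conc=float(config.get("syringe_conc_M", 300e-6)),
        noise_sigma=float(config.get("noise_sigma_ucal", 0.1)),
        n_replicates=int(config.get("n_replicates", 3)),
        seed=seed,
    )
    replicates = gen_replicates(spec)
    stages.append(
        {"stage": "simulate", "seed": seed, "n_replicates": len(replicates),
         "elapsed_s": round(time.perf_counter() - t0, 6)}
    )
    logger.info("simulated %d replicates (seed %d)", len(replicates), seed)

    t0 = time.perf_counter()
    exclude_first = bool(config.get("exclude_first", False))
    fits = [
        _fit_one(iso, model_kind, seed=seed + 1000 + i, exclude_first=exclude_first)
        for i, iso in enumerate(replicates)
    ]
    stages.append({"stage": "fit", "model": model_kind,
                   "elapsed_s": round(time.perf_counter() - t0, 6)})
    report["replicate_fits"] = [_fit_summary(f) for f in fits]

    t0 = time.perf_counter()
    keys = ["n", "kd", "dh"] if model_kind == "oss" else [
        "kd_intra", "kd_bridge", "h1", "h3"
    ]
    report["aggregated"] = _aggregate(fits, keys)
    stages.append({"stage": "aggregate", "elapsed_s": round(time.perf_counter() - t0, 6)})

    if "speciation" in config:
        t0 = time.perf_counter()
        sp = config["speciation"]
        model = LadderModel(
            q=int(sp.get("q", 3)),
            kd_intra=float(sp.get("kd_intra_M", 0.3e-6)),
            kd_bridge=float(sp.get("kd_bridge_M", 1.1e-6)),
            degeneracy=bool(sp.get("degeneracy", True)),
        )
        masses = MassTable.from_dict(config.get("mass_table", {}))
        state = speciate(
            float(sp.get("total_trimer_M", 10e-6)),
            float(sp.get("total_lc8_M", 30e-6)),
            model,
        )
        rows, mw = mass_profile(state, masses)
        report["speciation"] = {
            "free_trimer_M": state.free_trimer,
            "free_lc8_M": state.free_lc8,
            "bridged_fraction_of_trimer": state.bridged_fraction(),
            "weight_average_mass_kDa": mw,
            "species": [
                {"ratio": comp.ratio, "mass_kDa": m, "weight_fraction": w}
                for comp, m, w in rows
            ],
        }
        stages.append({"stage": "speciate",
                       "elapsed_s": round(time.perf_counter() - t0, 6)})
    return report
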