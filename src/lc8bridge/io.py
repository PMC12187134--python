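"""Plain-text isotherm format and configuration round-tripping.

An isotherm file is tab-separated with a YAML sidecar block in leading
``#`` comment lines carrying the injection schedule, temperature and any
metadata.  All units are fixed in the headers (uL, ucal, kcal/mol); there
is no unit inference.

    # lc8bridge-isotherm: 1
    # schedule:
    #   cell_volume_L: 0.0014
    #   ...
    injection_index  injection_volume_uL  heat_ucal  normalized_heat_kcal_per_mol  molar_ratio
    1  10.0  -31.2  -10.4  0.107
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .forward import InjectionSchedule, Isotherm

logger = logging.getLogger("lc8bridge")

FORMAT_KEY = "lc8bridge-isotherm"
FORMAT_VERSION = 1

REQUIRED_COLUMNS = (
    "injection_index",
    "injection_volume_uL",
    "heat_ucal",
    "normalized_heat_kcal_per_mol",
    "molar_ratio",
)


def write_isotherm(isotherm: Isotherm, path: str | Path) -> None:
    """Write an isotherm to the package's delimited-text format."""
    path = Path(path)
    header = {
        FORMAT_KEY: FORMAT_VERSION,
        "schedule": isotherm.schedule.to_dict(),
    }
    if isotherm.meta:
        header["meta"] = _plain(isotherm.meta)
    yaml_block = yaml.safe_dump(header, sort_keys=False, default_flow_style=False)
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, isotherm.n_injections + 1),
            "injection_volume_uL": np.asarray(isotherm.schedule.injection_volumes) * 1e6,
            "heat_ucal": isotherm.raw_heats,
            "normalized_heat_kcal_per_mol": isotherm.normalized_heats,
            "molar_ratio": isotherm.molar_ratios,
        }
    )
    with open(path, "w") as fh:
        for line in yaml_block.rstrip("\n").split("\n"):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_isotherm(path: str | Path) -> Isotherm:
    """Read an isotherm file, validating schema and invariants.

    Unknown extra columns are accepted with a logged warning; missing
    required columns, a bad header block, or a non-increasing molar-ratio
    axis raise :class:`ParseError` naming the problem.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such isotherm file: {path}")
    comment_lines, data_lines = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                comment_lines.append(line[2:])
            elif line.startswith("#"):
                comment_lines.append(line[1:])
            else:
                data_lines.append(line)
    try:
        header = yaml.safe_load("".join(comment_lines)) or {}
    except yaml.YAMLError as e:
        raise ParseError(f"{path}: invalid YAML header block: {e}") from e
    if header.get(FORMAT_KEY) != FORMAT_VERSION:
        raise ParseError(f"{path}: missing or unsupported '{FORMAT_KEY}' header")
    if "schedule" not in header:
        raise ParseError(f"{path}: header lacks the injection schedule")
    schedule = InjectionSchedule.from_dict(header["schedule"])

    try:
        df = pd.read_csv(_io.StringIO("".join(data_lines)), sep="\t")
    except Exception as e:
        raise ParseError(f"{path}: cannot parse data table: {e}") from e
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    ratios = df["molar_ratio"].to_numpy(float)
    bad = np.nonzero(np.diff(ratios) <= 0)[0]
    if bad.size:
        raise ParseError(
            f"{path}: molar_ratio not strictly increasing at data row {bad[0] + 2}"
        )
    vol_file = df["injection_volume_uL"].to_numpy(float) * 1e-6
    if not np.allclose(vol_file, schedule.injection_volumes, rtol=1e-9):
        raise ParseError(f"{path}: injection volumes disagree with the header schedule")
    return Isotherm(
        schedule=schedule,
        raw_heats=df["heat_ucal"].to_numpy(float),
        normalized_heats=df["normalized_heat_kcal_per_mol"].to_numpy(float),
        molar_ratios=ratios,
        meta=header.get("meta", {}) or {},
    )


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
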