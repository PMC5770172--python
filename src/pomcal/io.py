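"""File formats and run configuration.

Biomarker tables are plain CSV with exactly the seven biomarker columns
(comma-separated, ``.`` decimal, UTF-8, header required).  Populations of
models are CSV with ``#``-prefixed provenance comment lines (JSON) followed
by theta columns then biomarker columns, written at full float precision so
write/read round-trips are lossless.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .ap_model import BIOMARKER_NAMES, PARAMETER_NAMES, BiomarkerVector
from .refine import PopulationOfModels

logger = logging.getLogger("pomcal")


class FormatError(ValueError):
    pass


def _validate_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows violating the biomarker invariants, warning per row."""
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        try:
            BiomarkerVector(**{n: float(row[n]) for n in BIOMARKER_NAMES})
        except (ValueError, TypeError) as exc:
            keep[df.index.get_loc(i)] = False
            warnings.warn(f"row {i} rejected: {exc}", RuntimeWarning)
    return df[keep].reset_index(drop=True)


def read_biomarker_table(path) -> pd.DataFrame:
    """Read and validate a biomarker CSV.

    Missing biomarker columns raise a :class:`FormatError` naming the column;
    extra columns are ignored with a warning; rows violating the biomarker
    invariants are dropped with per-row warnings.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except ValueError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in BIOMARKER_NAMES:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    extra = [c for c in df.columns if c not in BIOMARKER_NAMES]
    if extra:
        warnings.warn(f"ignoring extra columns {extra}", RuntimeWarning)
    df = df[list(BIOMARKER_NAMES)]
    bad = df.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise FormatError(f"non-numeric value in row {r}, "
                          f"column {df.columns[c]!r}")
    return _validate_rows(df.astype(float))


def write_biomarker_table(df: pd.DataFrame, path) -> None:
    df[list(BIOMARKER_NAMES)].to_csv(path, index=False)


def write_population(pom: PopulationOfModels, path) -> None:
    """Population CSV: provenance comments, theta columns, biomarker columns."""
    path = Path(path)
    names = list(pom.parameter_names[:pom.theta.shape[1]])
    if pom.theta.shape[1] == 12:
        names = list(PARAMETER_NAMES) + ["tau_h_scale"]
    header = names + list(BIOMARKER_NAMES)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pomcal population of models\n")
        fh.write("# provenance: "
                 + json.dumps(pom.provenance, default=str) + "\n")
        fh.write(",".join(header) + "\n")
        for i in range(pom.size):
            vals = np.concatenate([pom.theta[i], pom.biomarkers[i]])
            fh.write(",".join(repr(float(v)) for v in vals) + "\n")


def read_population(path) -> PopulationOfModels:
    path = Path(path)
    provenance = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# provenance:"):
                provenance = json.loads(line.split(":", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = list(df.columns)
    for b in BIOMARKER_NAMES:
        if b not in cols:
            raise FormatError(f"population file missing biomarker column {b!r}")
    theta_cols = [c for c in cols if c not in BIOMARKER_NAMES]
    n_theta = len(theta_cols)
    if n_theta == 0:
        raise FormatError("population file has no parameter columns")
    return PopulationOfModels(
        theta=df[theta_cols].to_numpy(dtype=float).reshape(len(df), n_theta),
        biomarkers=df[list(BIOMARKER_NAMES)].to_numpy(dtype=float).reshape(
            len(df), len(BIOMARKER_NAMES)),
        parameter_names=tuple(theta_cols),
        provenance=provenance)


_KNOWN_KEYS = {
    "protocol": {"amplitude", "duration", "cycle_length", "steady_state_tol",
                 "extra_beats", "max_beats", "temperature", "Na_o", "K_o",
                 "Ca_o"},
    "solver": {"max_step", "rtol", "atol_scale", "method"},
    "smc": {"n_particles", "ess_fraction", "max_components", "seed"},
    "refinement": {"T", "check_interval", "restart_threshold", "min_size",
                   "step_budget", "bins", "norm", "mode"},
    "density": {"bandwidth_convention", "transforms"},
    "bounds": None,   # mapping parameter name -> [lo, hi]
}


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    for section, value in cfg.items():
        if section not in _KNOWN_KEYS:
            raise FormatError(f"unknown config section {section!r}")
        allowed = _KNOWN_KEYS[section]
        if allowed is not None and isinstance(value, dict):
            unknown = set(value) - allowed
            if unknown:
                raise FormatError(
                    f"unknown keys {sorted(unknown)} in section {section!r}")
        if section == "bounds":
            valid = set(PARAMETER_NAMES) | {"tau_h_scale"}
            unknown = set(value) - valid
            if unknown:
                raise FormatError(f"unknown bound entries {sorted(unknown)}")
    return cfg


def bounds_from_config(cfg: dict, include_tau_h: bool = False) -> np.ndarray:
    """Parameter bounds array (d, 2); defaults to [0, 2] for each multiplier."""
    names = list(PARAMETER_NAMES) + (["tau_h_scale"] if include_tau_h else [])
    spec = cfg.get("bounds", {}) or {}
    out = np.tile([0.0, 2.0], (len(names), 1))
    for k, name in enumerate(names):
        if name in spec:
            lo, hi = spec[name]
            out[k] = [float(lo), float(hi)]
    return out


def serialize_density(est, path) -> None:
    """Portable JSON serialization of a fitted density estimate."""
    payload = {
        "points": est.points.tolist(),
        "H": est.H.tolist(),
        "h_opt": est.h_opt,
        "log_dims": est.log_dims.astype(int).tolist(),
        "columns": list(est.columns),
        "bandwidth_convention": est.bandwidth_convention,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def deserialize_density(path):
    from .density import DensityEstimate
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return DensityEstimate(
        points=np.asarray(payload["points"], dtype=float),
        H=np.asarray(payload["H"], dtype=float),
        h_opt=payload["h_opt"],
        log_dims=np.asarray(payload["log_dims"], dtype=bool),
        columns=tuple(payload["columns"]),
        bandwidth_convention=payload["bandwidth_convention"])
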