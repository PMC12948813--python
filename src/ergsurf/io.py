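"""Reading and writing waveform tables and fitted models.

Waveform data travel as plain CSV with a fixed header
(subject_id,eye,group,flash_td_s,time_ms,amplitude_uv); files written by
this package carry '#'-prefixed provenance comment lines (tool version,
config hash, seed) which standard CSV readers skip.  Fitted models are
stored as versioned JSON containers with matrices row-major plus explicit
shape fields, so a reloaded model reproduces predictions exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ModelFormatError, SchemaError
from .gam import REQUIRED_COLUMNS, FittedGAM, ModelSpec, WaveformDataset
from .splines import KnotVector
from .tensor import ConstraintMap, TensorSmooth

MODEL_FORMAT_VERSION = 1


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed=None, config: dict | None = None) -> str:
    parts = [f"# ergsurf v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts)


def read_waveforms(path) -> WaveformDataset:
    """Read and validate a long-format waveform CSV.

    Raises a named validation error (SchemaError, NonNumericError,
    NonPositiveFlashError, DuplicateKeyError, NonMonotoneTimeError) on any
    invariant violation; rows come back sorted by (subject, eye, fs, t).
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#", dtype={"subject_id": str, "eye": str, "group": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return WaveformDataset(frame)


def write_waveforms(data: WaveformDataset, path, seed=None, config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        data.frame.to_csv(fh, index=False)


def write_frame(frame: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Write any result table as CSV with a provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        frame.to_csv(fh, index=False)


def _knots_to_dict(kv: KnotVector) -> dict:
    return {"knots": kv.knots.tolist(), "degree": int(kv.degree)}


def _knots_from_dict(d: dict) -> KnotVector:
    return KnotVector(knots=np.asarray(d["knots"], dtype=float), degree=int(d["degree"]))


def write_model(model: FittedGAM, path) -> None:
    """Serialize a fitted model to a versioned JSON container."""
    cov = np.asarray(model.coef_covariance, dtype=float)
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "group": model.group,
        "spec": {
            "k_t": model.spec.k_t, "k_fs": model.spec.k_fs,
            "degree": model.spec.degree, "penalty_order": model.spec.penalty_order,
            "fs_log_scale": model.spec.fs_log_scale,
            "random_effect_unit": model.spec.random_effect_unit,
            "lambda_bounds": list(model.spec.lambda_bounds),
            "n_grid": model.spec.n_grid, "nm_tol": model.spec.nm_tol,
            "nm_maxiter": model.spec.nm_maxiter, "seed": model.spec.seed,
        },
        "beta0": model.beta0,
        "random_effects": {
            "labels": list(model.random_effects.index),
            "values": model.random_effects.to_numpy().tolist(),
        },
        "smooth_coefs": model.smooth_coefs.tolist(),
        "lambdas": model.lambdas,
        "sigma2": model.sigma2,
        "sigma2_b": model.sigma2_b,
        "edf": model.edf,
        "gcv": model.gcv,
        "n_obs": model.n_obs,
        "data_ranges": model.data_ranges,
        "smooth": {
            "kv_t": _knots_to_dict(model.smooth.kv_t),
            "kv_fs": _knots_to_dict(model.smooth.kv_fs),
            "fs_log_scale": model.smooth.fs_log_scale,
            "constraint_c": model.smooth.cmap.c.tolist(),
        },
        "coef_covariance": {"shape": list(cov.shape), "data": cov.ravel().tolist()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_model(path) -> FittedGAM:
    """Load a fitted model; predictions round-trip exactly."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"{path}: truncated or invalid JSON ({e})") from e
    if "format_version" not in doc:
        raise ModelFormatError(f"{path}: missing format_version field")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported format_version {doc['format_version']} "
            f"(supported: {MODEL_FORMAT_VERSION})"
        )
    spec = ModelSpec(**{**doc["spec"], "lambda_bounds": tuple(doc["spec"]["lambda_bounds"])})
    sm = doc["smooth"]
    smooth = TensorSmooth(
        kv_t=_knots_from_dict(sm["kv_t"]),
        kv_fs=_knots_from_dict(sm["kv_fs"]),
        fs_log_scale=bool(sm["fs_log_scale"]),
        cmap=ConstraintMap(c=np.asarray(sm["constraint_c"], dtype=float)),
    )
    cov = np.asarray(doc["coef_covariance"]["data"], dtype=float).reshape(
        doc["coef_covariance"]["shape"]
    )
    return FittedGAM(
        beta0=float(doc["beta0"]),
        random_effects=pd.Series(
            np.asarray(doc["random_effects"]["values"], dtype=float),
            index=doc["random_effects"]["labels"],
            name="b",
        ),
        smooth_coefs=np.asarray(doc["smooth_coefs"], dtype=float),
        lambdas={k: float(v) for k, v in doc["lambdas"].items()},
        sigma2=float(doc["sigma2"]),
        sigma2_b=float(doc["sigma2_b"]),
        coef_covariance=cov,
        edf=float(doc["edf"]),
        gcv=float(doc["gcv"]),
        data_ranges={k: float(v) for k, v in doc["data_ranges"].items()},
        smooth=smooth,
        spec=spec,
        n_obs=int(doc["n_obs"]),
        group=doc.get("group", ""),
    )
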