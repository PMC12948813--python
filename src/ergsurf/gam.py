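"""Penalized-least-squares GAM engine for ERG waveform surfaces.

Fits the additive model

    Y_ijk = beta0 + b_i + f(t_ijk, FS_ij) + eps_ijk

where f is a tensor-product P-spline surface over time (ms) and flash
strength (Td.s), b_i is a random per-recording-unit intercept encoded as a
ridge-penalized coefficient block (b_i ~ N(0, sigma_b^2) with
sigma_b^2 = sigma^2 / lambda_b), and eps is Gaussian noise.  All three
penalty weights (lambda_t, lambda_fs, lambda_b) are chosen jointly by
minimizing the GCV criterion  n * RSS / (n - tr(A))^2  over a multi-start
log-scale grid followed by Nelder-Mead refinement, so fits are
deterministic given a :class:`ModelSpec`.

Coefficient uncertainty uses the Bayesian posterior covariance of the
penalized fit, (X'X + sum lambda_j S_j)^{-1} * sigma^2, the standard
convention for penalized regression splines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_solve, lapack

from .errors import (
    DuplicateKeyError,
    NonMonotoneTimeError,
    NonNumericError,
    NonPositiveFlashError,
    OptimizationError,
    PredictionRangeError,
    SaturatedFitError,
    SchemaError,
    SingularModelError,
)
from .splines import bspline_design, difference_penalty, place_knots
from .tensor import TensorSmooth, apply_constraint, row_kronecker, tensor_penalties

REQUIRED_COLUMNS = ["subject_id", "eye", "group", "flash_td_s", "time_ms", "amplitude_uv"]
NUMERIC_COLUMNS = ["flash_td_s", "time_ms", "amplitude_uv"]


# ---------------------------------------------------------------------------
# data container


@dataclass
class WaveformDataset:
    """Long-format ERG observations: one row per sampled point.

    Columns: subject_id, eye, group (labels); flash_td_s (Td.s > 0);
    time_ms (ms); amplitude_uv (µV).  Each (subject, eye, flash) series must
    be strictly increasing in time with no missing amplitudes.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = validate_waveforms(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def subset(self, group: str) -> "WaveformDataset":
        sub = self.frame[self.frame["group"] == group]
        if sub.empty:
            raise ValueError(f"no rows for group {group!r}; have {self.groups}")
        return WaveformDataset(sub.reset_index(drop=True))

    def n_waveforms(self) -> int:
        return self.frame.groupby(["subject_id", "eye", "flash_td_s"], observed=True).ngroups


def validate_waveforms(frame: pd.DataFrame) -> pd.DataFrame:
    """Enforce dataset invariants; returns rows sorted by (subject, eye, fs, t)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    frame = frame[REQUIRED_COLUMNS].copy()
    for col in NUMERIC_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise NonNumericError(f"column {col!r} non-numeric or missing at row {bad}")
        frame[col] = vals.astype(float)
    if (frame["flash_td_s"] <= 0).any():
        bad = int(np.flatnonzero((frame["flash_td_s"] <= 0).to_numpy())[0])
        raise NonPositiveFlashError(f"flash_td_s must be > 0 (row {bad})")
    frame = frame.sort_values(
        ["subject_id", "eye", "flash_td_s", "time_ms"], kind="mergesort"
    ).reset_index(drop=True)
    keys = frame[["subject_id", "eye", "flash_td_s", "time_ms"]]
    if keys.duplicated().any():
        bad = int(np.flatnonzero(keys.duplicated().to_numpy())[0])
        raise DuplicateKeyError(f"duplicated (subject, eye, flash, time) key at sorted row {bad}")
    dt = frame.groupby(["subject_id", "eye", "flash_td_s"], observed=True)["time_ms"].diff()
    if (dt.dropna() <= 0).any():
        raise NonMonotoneTimeError("a (subject, eye, flash) series is not strictly increasing in time")
    return frame


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the surface GAM.

    k_t / k_fs are marginal basis dimensions (time resolves the a-wave
    trough, oscillatory-potential ripples and b-wave rise inside a ~52 ms
    window, so it gets the larger basis; FS has only 10 design levels so
    k_fs stays below 10).  The three smoothing weights are searched on
    log10 scale over ``lambda_bounds`` with ``n_grid`` multi-start points
    per axis, then refined by Nelder-Mead.
    """

    k_t: int = 20
    k_fs: int = 8
    degree: int = 3
    penalty_order: int = 2
    fs_log_scale: bool = False
    random_effect_unit: str = "per_subject"  # or "per_eye"
    lambda_bounds: tuple[float, float] = (-6.0, 6.0)
    n_grid: int = 5
    nm_tol: float = 1e-6
    nm_maxiter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_t < self.degree + 1 or self.k_fs < self.degree + 1:
            raise ValueError("k_t and k_fs must be >= degree + 1")
        lo, hi = self.lambda_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError("lambda_bounds must be finite with hi > lo")
        if self.random_effect_unit not in ("per_subject", "per_eye"):
            raise ValueError("random_effect_unit must be 'per_subject' or 'per_eye'")


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class DesignBundle:
    """Assembled response, design blocks and penalties for one group fit."""

    y: np.ndarray
    blocks: dict[str, np.ndarray]          # intercept, random, smooth
    penalties: list[np.ndarray]            # full-size: [S_t, S_fs, S_b]
    unit_labels: list[str]
    smooth: TensorSmooth
    data_ranges: dict[str, float]

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.blocks["intercept"], self.blocks["random"], self.blocks["smooth"]])

    @property
    def n_units(self) -> int:
        return len(self.unit_labels)


def assemble_design(data: WaveformDataset, spec: ModelSpec) -> DesignBundle:
    """Build [intercept | random-effect indicators | constrained tensor] design.

    The random-effect block carries an identity penalty (weight lambda_b);
    the constrained tensor block carries the two directional penalties
    (lambda_t, lambda_fs).  Knots span the observed data rectangle exactly,
    so prediction is confined to the fitted range.
    """
    df = data.frame
    t = df["time_ms"].to_numpy()
    fs = df["flash_td_s"].to_numpy()
    y = df["amplitude_uv"].to_numpy()
    n = len(df)

    if spec.random_effect_unit == "per_subject":
        unit = df["subject_id"].astype(str)
    else:
        unit = df["subject_id"].astype(str) + "/" + df["eye"].astype(str)
    unit_labels = sorted(unit.unique())
    if len(unit_labels) < 2:
        raise ValueError("need >= 2 random-effect units to estimate sigma_b")
    codes = pd.Categorical(unit, categories=unit_labels).codes
    R = np.zeros((n, len(unit_labels)))
    R[np.arange(n), codes] = 1.0

    kv_t = place_knots(t.min(), t.max(), spec.k_t, spec.degree)
    fs_coord = np.log10(fs) if spec.fs_log_scale else fs
    kv_fs = place_knots(fs_coord.min(), fs_coord.max(), spec.k_fs, spec.degree)
    B = row_kronecker(bspline_design(t, kv_t), bspline_design(fs_coord, kv_fs))
    S_t = difference_penalty(spec.k_t, spec.penalty_order)
    S_fs = difference_penalty(spec.k_fs, spec.penalty_order)
    P_t, P_fs = tensor_penalties(S_t, S_fs)
    Bc, (P_t_c, P_fs_c), cmap = apply_constraint(B, (P_t, P_fs))

    smooth = TensorSmooth(kv_t=kv_t, kv_fs=kv_fs, fs_log_scale=spec.fs_log_scale, cmap=cmap)
    p = 1 + len(unit_labels) + Bc.shape[1]
    off_r = 1
    off_s = 1 + len(unit_labels)
    S_t_full = np.zeros((p, p))
    S_t_full[off_s:, off_s:] = P_t_c
    S_fs_full = np.zeros((p, p))
    S_fs_full[off_s:, off_s:] = P_fs_c
    S_b_full = np.zeros((p, p))
    S_b_full[off_r:off_s, off_r:off_s] = np.eye(len(unit_labels))

    ranges = {
        "t_min": float(t.min()), "t_max": float(t.max()),
        "fs_min": float(fs.min()), "fs_max": float(fs.max()),
    }
    return DesignBundle(
        y=y,
        blocks={"intercept": np.ones((n, 1)), "random": R, "smooth": Bc},
        penalties=[S_t_full, S_fs_full, S_b_full],
        unit_labels=list(unit_labels),
        smooth=smooth,
        data_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# penalized solver and GCV

# A very large but benign ridge weight (e.g. lambda_b -> 1e12 to disable the
# random-effect block) legitimately drives the 1-norm condition past 1e12, so
# the guard only rejects conditioning at the edge of double precision.
_RCOND_FLOOR = 1e-14


def _penalized_normal_solve(XtX, Xty, penalties, lambdas):
    """Solve (X'X + sum lam_j S_j) beta = X'y; return (beta, chol, A)."""
    A = XtX.copy()
    for lam, S in zip(lambdas, penalties):
        if S is None:
            continue
        A += lam * S
    L, info = lapack.dpotrf(A, lower=1)
    if info != 0:
        raise SingularModelError("penalized normal matrix is not positive definite")
    anorm = np.linalg.norm(A, 1)
    rcond, info = lapack.dpocon(L, anorm, uplo="L")
    if info != 0 or rcond < _RCOND_FLOOR:
        raise SingularModelError(f"penalized normal matrix ill-conditioned (rcond={rcond:.2e})")
    beta, info = lapack.dpotrs(L, Xty, lower=1)
    if info != 0:
        raise SingularModelError("triangular solve failed")
    return beta, L


def solve_penalized(X, y, penalties, lambdas):
    """Penalized least squares: min ||y - X b||^2 + sum_j lam_j b' S_j b.

    Returns ``(coefficients, hat_trace, rss)`` where hat_trace is
    tr[X (X'X + sum lam_j S_j)^{-1} X'], the effective degrees of freedom.
    Entries of ``penalties`` may be None (unpenalized block placeholder);
    the matching lambda is ignored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    Xty = X.T @ y
    beta, L = _penalized_normal_solve(XtX, Xty, penalties, lambdas)
    hat_trace = float(np.trace(cho_solve((L, True), XtX)))
    resid = y - X @ beta
    return beta, hat_trace, float(resid @ resid)


def gcv_score(rss: float, n: int, hat_trace: float) -> float:
    """Generalized cross validation criterion n * RSS / (n - tr(A))^2."""
    if n <= hat_trace:
        raise SaturatedFitError(f"edf {hat_trace:.2f} >= n {n}: GCV undefined")
    return n * rss / (n - hat_trace) ** 2


class _GCVObjective:
    """GCV as a function of log10 lambdas, over precomputed cross-products."""

    def __init__(self, XtX, Xty, yty, n, penalties):
        self.XtX, self.Xty, self.yty, self.n = XtX, Xty, yty, n
        self.penalties = penalties

    def parts(self, log10_lam):
        lam = 10.0 ** np.asarray(log10_lam, dtype=float)
        beta, L = _penalized_normal_solve(self.XtX, self.Xty, self.penalties, lam)
        hat_trace = float(np.trace(cho_solve((L, True), self.XtX)))
        rss = float(self.yty - 2.0 * beta @ self.Xty + beta @ self.XtX @ beta)
        rss = max(rss, 0.0)
        return beta, L, hat_trace, rss

    def __call__(self, log10_lam) -> float:
        try:
            _, _, hat_trace, rss = self.parts(log10_lam)
            return gcv_score(rss, self.n, hat_trace)
        except (SingularModelError, SaturatedFitError):
            return np.inf


def optimize_lambdas(X, y, penalties, spec: ModelSpec):
    """GCV-optimal (lambda_t, lambda_fs, lambda_b) by grid multi-start + Nelder-Mead.

    Deterministic given ``spec``; the returned point is never worse than the
    best multi-start grid evaluation.  Returns ``(lambdas, gcv)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    obj = _GCVObjective(X.T @ X, X.T @ y, float(y @ y), len(y), penalties)
    log_lam, gcv = _search_lambdas(obj, spec)
    return 10.0 ** log_lam, gcv


def _search_lambdas(obj: _GCVObjective, spec: ModelSpec):
    lo, hi = spec.lambda_bounds
    axis = np.linspace(lo, hi, spec.n_grid)
    best_val = np.inf
    best_pt = None
    for a in axis:
        for b in axis:
            for c in axis:
                v = obj((a, b, c))
                if v < best_val:
                    best_val, best_pt = v, np.array([a, b, c])
    if best_pt is None or not np.isfinite(best_val):
        raise OptimizationError("GCV criterion non-finite at every multi-start grid point")
    # refine on log(GCV) for scale-free tolerances
    res = optimize.minimize(
        lambda p: np.log(max(obj(p), np.finfo(float).tiny)),
        best_pt,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": spec.nm_tol, "maxiter": spec.nm_maxiter},
    )
    refined_val = obj(res.x)
    if np.isfinite(refined_val) and refined_val <= best_val:
        return np.asarray(res.x, dtype=float), float(refined_val)
    return best_pt, float(best_val)


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedGAM:
    """Fitted surface model with coefficient uncertainty.

    Coefficient layout (matching ``coef_covariance``):
    index 0 = intercept beta0, indices 1..n_units = random effects b,
    remainder = constrained tensor-smooth coefficients.
    """

    beta0: float
    random_effects: pd.Series
    smooth_coefs: np.ndarray
    lambdas: dict[str, float]              # lambda_t, lambda_fs, lambda_b
    sigma2: float
    sigma2_b: float
    coef_covariance: np.ndarray
    edf: float
    gcv: float
    data_ranges: dict[str, float]
    smooth: TensorSmooth
    spec: ModelSpec
    n_obs: int
    group: str = ""

    @property
    def n_units(self) -> int:
        return len(self.random_effects)

    @property
    def sigma_b(self) -> float:
        return float(np.sqrt(self.sigma2_b))


def fit_gam(data: WaveformDataset, spec: ModelSpec = ModelSpec(), group: str = "") -> FittedGAM:
    """Assemble, select smoothing parameters by GCV, and solve.

    sigma^2 is estimated as RSS / (n - edf); the random-effect variance
    follows from the selected ridge weight, sigma_b^2 = sigma^2 / lambda_b.
    """
    bundle = assemble_design(data, spec)
    X = bundle.X
    y = bundle.y
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    obj = _GCVObjective(XtX, Xty, float(y @ y), n, bundle.penalties)
    log_lam, gcv = _search_lambdas(obj, spec)
    lam = 10.0 ** log_lam

    beta, L = _penalized_normal_solve(XtX, Xty, bundle.penalties, lam)
    hat_trace = float(np.trace(cho_solve((L, True), XtX)))
    resid = y - X @ beta
    rss = float(resid @ resid)
    if n <= hat_trace:
        raise SaturatedFitError("model saturated: edf >= n")
    if hat_trace > 0.99 * p:
        warnings.warn(
            f"edf {hat_trace:.1f} within 1% of coefficient count {p}: possible undersmoothing",
            stacklevel=2,
        )
    sigma2 = rss / (n - hat_trace)
    sigma2_b = sigma2 / lam[2]
    Ainv = cho_solve((L, True), np.eye(p))
    cov = sigma2 * 0.5 * (Ainv + Ainv.T)  # symmetrize roundoff

    n_units = bundle.n_units
    return FittedGAM(
        beta0=float(beta[0]),
        random_effects=pd.Series(beta[1 : 1 + n_units], index=bundle.unit_labels, name="b"),
        smooth_coefs=beta[1 + n_units :].copy(),
        lambdas={"lambda_t": float(lam[0]), "lambda_fs": float(lam[1]), "lambda_b": float(lam[2])},
        sigma2=float(sigma2),
        sigma2_b=float(sigma2_b),
        coef_covariance=cov,
        edf=hat_trace,
        gcv=float(gcv),
        data_ranges=bundle.data_ranges,
        smooth=bundle.smooth,
        spec=spec,
        n_obs=n,
        group=group or (data.groups[0] if len(data.groups) == 1 else ""),
    )


def _check_range(model: FittedGAM, t: np.ndarray, fs: np.ndarray) -> None:
    r = model.data_ranges
    tol_t = 1e-9 * max(1.0, abs(r["t_max"]))
    tol_f = 1e-9 * max(1.0, abs(r["fs_max"]))
    if np.any(t < r["t_min"] - tol_t) or np.any(t > r["t_max"] + tol_t):
        raise PredictionRangeError(
            f"time outside fitted range [{r['t_min']:.5f}, {r['t_max']:.5f}] ms"
        )
    if np.any(fs < r["fs_min"] - tol_f) or np.any(fs > r["fs_max"] + tol_f):
        bad = np.asarray(fs)[(np.asarray(fs) < r["fs_min"] - tol_f) | (np.asarray(fs) > r["fs_max"] + tol_f)]
        raise PredictionRangeError(
            f"flash strength {np.atleast_1d(bad)[0]:g} outside fitted range "
            f"[{r['fs_min']:g}, {r['fs_max']:g}] Td.s"
        )


def predict_with_se(model: FittedGAM, t, fs):
    """Population-level prediction beta0 + f(t, fs) with its standard error.

    Random effects are set to zero (population mean); the SE propagates the
    posterior covariance of (beta0, smooth coefficients) through the
    prediction row.  Accepts scalars or equal-length arrays; no
    extrapolation outside the fitted rectangle.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    fs_arr = np.atleast_1d(np.asarray(fs, dtype=float))
    t_arr, fs_arr = np.broadcast_arrays(t_arr, fs_arr)
    _check_range(model, t_arr, fs_arr)
    # clip roundoff-level overshoot so boundary points evaluate cleanly
    r = model.data_ranges
    t_arr = np.clip(t_arr, r["t_min"], r["t_max"])
    fs_arr = np.clip(fs_arr, r["fs_min"], r["fs_max"])

    Bc = model.smooth.design_rows(t_arr.ravel(), fs_arr.ravel())
    est = model.beta0 + Bc @ model.smooth_coefs
    idx = np.concatenate([[0], np.arange(1 + model.n_units, model.coef_covariance.shape[0])])
    V = model.coef_covariance[np.ix_(idx, idx)]
    Xp = np.hstack([np.ones((Bc.shape[0], 1)), Bc])
    var = np.einsum("ij,jk,ik->i", Xp, V, Xp)
    se = np.sqrt(np.maximum(var, 0.0))
    est = est.reshape(t_arr.shape)
    se = se.reshape(t_arr.shape)
    if np.isscalar(t) and np.isscalar(fs):
        return float(est.ravel()[0]), float(se.ravel()[0])
    return est, se
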