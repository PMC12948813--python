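"""Surface-level outputs of fitted models.

Turns one or two fitted models into the quantities a reader of the
stimulus-response surface cares about: the estimated amplitude surface
f(t, FS) with pointwise standard errors on a rectangular grid, the
between-group difference surface with SEs combined in quadrature (the two
groups are fitted independently), the pointwise z-score map, model-derived
waveforms at arbitrary in-range flash strengths, grid extrema, and contour
polylines extracted by marching squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .errors import PredictionRangeError
from .gam import FittedGAM, predict_with_se

#: Flash strengths (Td.s) at which modelled waveforms are derived by default.
DEFAULT_WAVEFORM_FS = (15.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 300.0, 400.0)


@dataclass
class SurfaceGrid:
    """Population-mean amplitude estimates and SEs on a (t, FS) grid.

    ``estimate[i, j]`` is beta0 + f(t_axis[i], fs_axis[j]) in µV.
    """

    t_axis: np.ndarray
    fs_axis: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (time_ms, flash_td_s, estimate_uv, se_uv)."""
        tt, ff = np.meshgrid(self.t_axis, self.fs_axis, indexing="ij")
        return pd.DataFrame({
            "time_ms": tt.ravel(),
            "flash_td_s": ff.ravel(),
            "estimate_uv": self.estimate.ravel(),
            "se_uv": self.se.ravel(),
        })


@dataclass
class DifferenceSurface:
    """Pointwise A - B difference between two independently fitted surfaces."""

    t_axis: np.ndarray
    fs_axis: np.ndarray
    diff: np.ndarray
    se_diff: np.ndarray
    z: np.ndarray
    source_a: str = ""
    source_b: str = ""

    def to_frame(self) -> pd.DataFrame:
        tt, ff = np.meshgrid(self.t_axis, self.fs_axis, indexing="ij")
        return pd.DataFrame({
            "time_ms": tt.ravel(),
            "flash_td_s": ff.ravel(),
            "diff_uv": self.diff.ravel(),
            "se_diff_uv": self.se_diff.ravel(),
            "z": self.z.ravel(),
        })


def _default_axes(ranges: dict[str, float], n_t: int, n_fs: int):
    return (
        np.linspace(ranges["t_min"], ranges["t_max"], n_t),
        np.linspace(ranges["fs_min"], ranges["fs_max"], n_fs),
    )


def evaluate_surface(
    model: FittedGAM,
    t_axis=None,
    fs_axis=None,
    n_t: int = 200,
    n_fs: int = 100,
) -> SurfaceGrid:
    """Evaluate the fitted surface (including the intercept) on a grid.

    Default grid: ``n_t`` x ``n_fs`` points spanning the fitted rectangle.
    """
    if t_axis is None or fs_axis is None:
        dt, dfs = _default_axes(model.data_ranges, n_t, n_fs)
        t_axis = dt if t_axis is None else np.asarray(t_axis, dtype=float)
        fs_axis = dfs if fs_axis is None else np.asarray(fs_axis, dtype=float)
    t_axis = np.atleast_1d(np.asarray(t_axis, dtype=float))
    fs_axis = np.atleast_1d(np.asarray(fs_axis, dtype=float))
    if np.any(np.diff(t_axis) <= 0) or (len(fs_axis) > 1 and np.any(np.diff(fs_axis) <= 0)):
        raise ValueError("grid axes must be strictly increasing")
    tt, ff = np.meshgrid(t_axis, fs_axis, indexing="ij")
    est, se = predict_with_se(model, tt.ravel(), ff.ravel())
    return SurfaceGrid(
        t_axis=t_axis,
        fs_axis=fs_axis,
        estimate=est.reshape(tt.shape),
        se=se.reshape(tt.shape),
        source=model.group,
    )


def difference_surface(
    model_a: FittedGAM,
    model_b: FittedGAM,
    t_axis=None,
    fs_axis=None,
    n_t: int = 200,
    n_fs: int = 100,
) -> DifferenceSurface:
    """A - B surface on the intersection of the two fitted rectangles.

    The models are fitted independently, so the SE of the difference is the
    quadrature combination sqrt(se_A^2 + se_B^2); z = diff / se_diff.
    """
    ra, rb = model_a.data_ranges, model_b.data_ranges
    inter = {
        "t_min": max(ra["t_min"], rb["t_min"]), "t_max": min(ra["t_max"], rb["t_max"]),
        "fs_min": max(ra["fs_min"], rb["fs_min"]), "fs_max": min(ra["fs_max"], rb["fs_max"]),
    }
    if inter["t_min"] >= inter["t_max"] or inter["fs_min"] >= inter["fs_max"]:
        raise PredictionRangeError("fitted (t, FS) rectangles do not overlap")
    if t_axis is None or fs_axis is None:
        dt, dfs = _default_axes(inter, n_t, n_fs)
        t_axis = dt if t_axis is None else np.asarray(t_axis, dtype=float)
        fs_axis = dfs if fs_axis is None else np.asarray(fs_axis, dtype=float)
    ga = evaluate_surface(model_a, t_axis, fs_axis)
    gb = evaluate_surface(model_b, t_axis, fs_axis)
    diff = ga.estimate - gb.estimate
    se_diff = np.sqrt(ga.se**2 + gb.se**2)
    return DifferenceSurface(
        t_axis=ga.t_axis,
        fs_axis=ga.fs_axis,
        diff=diff,
        se_diff=se_diff,
        z=diff / se_diff,
        source_a=model_a.group,
        source_b=model_b.group,
    )


def zscore_surface(d: DifferenceSurface) -> np.ndarray:
    """Pointwise z = diff / se_diff (recomputed from the stored grids)."""
    if np.any(d.se_diff <= 0):
        raise ValueError("se_diff must be strictly positive")
    return d.diff / d.se_diff


def derived_waveforms(
    model: FittedGAM,
    fs_list=DEFAULT_WAVEFORM_FS,
    t_axis=None,
    n_t: int = 200,
) -> pd.DataFrame:
    """Model-derived waveforms at chosen flash strengths (within range only).

    Returns a long table (flash_td_s, time_ms, estimate_uv, se_uv) sharing
    the prediction path of :func:`evaluate_surface`.
    """
    if t_axis is None:
        t_axis = np.linspace(model.data_ranges["t_min"], model.data_ranges["t_max"], n_t)
    t_axis = np.asarray(t_axis, dtype=float)
    rows = []
    for fs in fs_list:
        est, se = predict_with_se(model, t_axis, np.full_like(t_axis, float(fs)))
        rows.append(pd.DataFrame({
            "flash_td_s": float(fs),
            "time_ms": t_axis,
            "estimate_uv": est,
            "se_uv": se,
        }))
    return pd.concat(rows, ignore_index=True)


def locate_extrema(grid: SurfaceGrid) -> dict[str, tuple[float, float, float]]:
    """Global min and max of the estimate grid as (t, fs, value) triples.

    Ties are broken toward the smallest t, then the smallest fs (row-major
    first occurrence on the (t, fs)-ordered grid).
    """
    est = grid.estimate
    if est.size == 0:
        raise ValueError("empty grid")
    imin = np.unravel_index(np.argmin(est), est.shape)
    imax = np.unravel_index(np.argmax(est), est.shape)
    return {
        "min": (float(grid.t_axis[imin[0]]), float(grid.fs_axis[imin[1]]), float(est[imin])),
        "max": (float(grid.t_axis[imax[0]]), float(grid.fs_axis[imax[1]]), float(est[imax])),
    }


def contour_levels(grid: SurfaceGrid, levels) -> dict[float, list[np.ndarray]]:
    """Iso-amplitude polylines by marching squares, in data coordinates.

    Returns ``{level: [polyline, ...]}`` with each polyline an (m, 2) array
    of (time_ms, flash_td_s) vertices; vertices interpolate grid cells
    straddling the level.  Out-of-range levels yield empty lists.
    """
    out: dict[float, list[np.ndarray]] = {}
    nt = len(grid.t_axis)
    nfs = len(grid.fs_axis)
    for level in levels:
        level = float(level)
        if not (grid.estimate.min() < level < grid.estimate.max()):
            out[level] = []
            continue
        polys = measure.find_contours(grid.estimate, level)
        mapped = []
        for poly in polys:
            t = np.interp(poly[:, 0], np.arange(nt), grid.t_axis)
            fs = np.interp(poly[:, 1], np.arange(nfs), grid.fs_axis)
            mapped.append(np.column_stack([t, fs]))
        out[level] = mapped
    return out


def contours_to_frame(contours: dict[float, list[np.ndarray]]) -> pd.DataFrame:
    """Flatten contour polylines to (level, polyline_id, vertex_index, t, fs)."""
    rows = []
    for level in sorted(contours):
        for pid, poly in enumerate(contours[level]):
            for vi, (t, fs) in enumerate(poly):
                rows.append((level, pid, vi, t, fs))
    return pd.DataFrame(
        rows, columns=["level", "polyline_id", "vertex_index", "time_ms", "flash_td_s"]
    )
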