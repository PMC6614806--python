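"""Spot detection, trajectory linking, and MSD diffusion estimation.

The front half of the binding-event identification pipeline: localize
fluorescent spots per frame, link them into per-molecule trajectories with
a deterministic greedy nearest-neighbour pass, and estimate a diffusion
coefficient per trajectory from the short-lag time-averaged MSD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "DiffusionEstimate",
    "detect_spots",
    "link_trajectories",
    "estimate_diffusion",
    "estimate_diffusion_table",
    "msd_per_lag",
    "ensemble_msd_slope",
]

DEFAULT_MIN_TRACK_LENGTH = 10
DEFAULT_N_LAGS = 4


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection configuration.

    ``threshold_sd`` sets the candidate threshold as a multiple of the
    robust background SD above the background median; band-pass widths are
    in pixels; ``refine_radius`` is the half-width of the centroid window.
    """

    dog_low: float = 1.0
    dog_high: float = 4.0
    threshold_sd: float = 5.0
    min_separation: int = 3
    refine_radius: int = 3
    pixel_size: float = 0.1


@dataclass
class DiffusionEstimate:
    """Per-trajectory diffusion coefficient from an MSD fit."""

    trajectory_id: int
    d_hat: float
    se_d: float
    n_points: int
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.d_hat < 0:
            raise ValueError("d_hat must be non-negative")


def detect_spots(
    stack: np.ndarray,
    params: DetectionParams = DetectionParams(),
    video_index: int = 0,
) -> pd.DataFrame:
    """Detect and localize spots in a grayscale image stack.

    Difference-of-Gaussians band-pass, local maxima above
    ``threshold_sd`` robust background SDs, then sub-pixel centroid
    refinement on the band-passed image.  Returns one row per detection
    with pixel and physical coordinates.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("stack must be a non-empty (frames, y, x) array")
    rows: list[dict] = []
    for f, frame in enumerate(stack):
        img = frame.astype(float)
        bp = ndimage.gaussian_filter(img, params.dog_low) - ndimage.gaussian_filter(
            img, params.dog_high
        )
        med = np.median(bp)
        mad = np.median(np.abs(bp - med))
        sd = 1.4826 * mad if mad > 0 else bp.std()
        thresh = med + params.threshold_sd * sd
        peaks = peak_local_max(
            bp, min_distance=params.min_separation, threshold_abs=thresh
        )
        r = params.refine_radius
        for py, px in peaks:
            y0, y1 = max(py - r, 0), min(py + r + 1, bp.shape[0])
            x0, x1 = max(px - r, 0), min(px + r + 1, bp.shape[1])
            win = np.clip(bp[y0:y1, x0:x1] - med, 0.0, None)
            total = win.sum()
            if total <= 0:
                continue
            gy, gx = np.mgrid[y0:y1, x0:x1]
            cy = float((gy * win).sum() / total)
            cx = float((gx * win).sum() / total)
            var = (
                ((gx - cx) ** 2 + (gy - cy) ** 2) * win
            ).sum() / total
            rows.append(
                {
                    "video_index": video_index,
                    "frame": f,
                    "x_px": cx,
                    "y_px": cy,
                    "x_um": cx * params.pixel_size,
                    "y_um": cy * params.pixel_size,
                    "intensity": float(total),
                    "width_um": float(np.sqrt(max(var, 0.0) / 2.0))
                    * params.pixel_size,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "video_index",
            "frame",
            "x_px",
            "y_px",
            "x_um",
            "y_um",
            "intensity",
            "width_um",
        ],
    )


def link_trajectories(
    detections: pd.DataFrame,
    max_disp: float,
    max_gap: int = 1,
    coord_cols: tuple[str, str] = ("x_um", "y_um"),
) -> pd.DataFrame:
    """Link detections into trajectories by greedy nearest-neighbour search.

    Frame-by-frame: candidate links between open track heads (within
    ``max_gap`` frames) and current detections are sorted by displacement
    (ties broken by lower detection index, then lower track id) and
    accepted greedily if displacement <= ``max_disp``.  Unlinked detections
    seed new trajectories.  Deterministic given the input ordering.

    Returns the detections table with a ``trajectory_id`` column added.
    Videos are linked independently when a ``video_index`` column is
    present (bursts are separated by long dark gaps).
    """
    if detections.empty:
        out = detections.copy()
        out["trajectory_id"] = pd.Series(dtype=int)
        return out
    xcol, ycol = coord_cols
    det = detections.reset_index(drop=True).copy()
    det["trajectory_id"] = -1
    next_tid = 0
    groups = (
        det.groupby("video_index", sort=True)
        if "video_index" in det.columns
        else [(0, det)]
    )
    for _, vid in groups:
        # open tracks: tid -> (last_frame, x, y)
        heads: dict[int, tuple[int, float, float]] = {}
        for frame, fdet in vid.groupby("frame", sort=True):
            idxs = fdet.index.to_numpy()
            xs = fdet[xcol].to_numpy(dtype=float)
            ys = fdet[ycol].to_numpy(dtype=float)
            candidates = []
            for tid, (lf, hx, hy) in heads.items():
                gap = frame - lf
                if gap > max_gap + 1:
                    continue
                d = np.hypot(xs - hx, ys - hy)
                for j in range(len(idxs)):
                    if d[j] <= max_disp:
                        candidates.append((d[j], j, tid))
            candidates.sort(key=lambda c: (c[0], c[1], c[2]))
            used_det: set[int] = set()
            used_tid: set[int] = set()
            for d, j, tid in candidates:
                if j in used_det or tid in used_tid:
                    continue
                used_det.add(j)
                used_tid.add(tid)
                det.loc[idxs[j], "trajectory_id"] = tid
                heads[tid] = (frame, xs[j], ys[j])
            for j in range(len(idxs)):
                if j not in used_det:
                    det.loc[idxs[j], "trajectory_id"] = next_tid
                    heads[next_tid] = (frame, xs[j], ys[j])
                    next_tid += 1
            # retire tracks that fell outside the gap window
            heads = {
                tid: h for tid, h in heads.items() if frame - h[0] <= max_gap
            }
    return det


def msd_per_lag(
    x: np.ndarray, y: np.ndarray, n_lags: int
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD at lags 1..n_lags for one trajectory.

    Returns (msd, n_pairs); lags with no pairs get NaN.  MSD at lag 0 is 0
    by construction and is not returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    msd = np.full(n_lags, np.nan)
    npairs = np.zeros(n_lags, dtype=int)
    for lag in range(1, n_lags + 1):
        if lag >= len(x):
            break
        dx = x[lag:] - x[:-lag]
        dy = y[lag:] - y[:-lag]
        msd[lag - 1] = np.mean(dx**2 + dy**2)
        npairs[lag - 1] = len(dx)
    return msd, npairs


def _fit_msd_slope(
    lags_t: np.ndarray, msd: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted through-origin fit of MSD = slope * lag_time."""
    w = weights
    denom = np.sum(w * lags_t**2)
    slope = float(np.sum(w * lags_t * msd) / denom)
    resid = msd - slope * lags_t
    dof = max(len(msd) - 1, 1)
    var_slope = float(np.sum(w * resid**2) / dof / denom)
    return slope, np.sqrt(max(var_slope, 0.0))


def estimate_diffusion(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    n_lags: int = DEFAULT_N_LAGS,
    trajectory_id: int = 0,
    min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
) -> DiffusionEstimate | None:
    """Estimate D from the short-lag MSD of one trajectory.

    Fits ``MSD(lag) = 4*D*lag*dt`` through the origin by weighted least
    squares over lags 1..n_lags (weights = pair counts).  Negative fitted
    slopes clamp to D = 0 with ``clamped=True``.  Trajectories shorter than
    ``min_track_length`` are skipped (returns None, logs a warning).
    """
    n = len(x)
    if n < min_track_length:
        logger.warning(
            "trajectory %d too short for diffusion estimate (%d < %d)",
            trajectory_id,
            n,
            min_track_length,
        )
        return None
    msd, npairs = msd_per_lag(x, y, n_lags)
    ok = npairs > 0
    lags_t = (np.arange(1, n_lags + 1)[ok]) * dt
    slope, se_slope = _fit_msd_slope(lags_t, msd[ok], npairs[ok].astype(float))
    d_hat = slope / 4.0
    se_d = se_slope / 4.0
    clamped = False
    if d_hat < 0:
        d_hat = 0.0
        clamped = True
    return DiffusionEstimate(
        trajectory_id=trajectory_id,
        d_hat=float(d_hat),
        se_d=float(se_d),
        n_points=n,
        clamped=clamped,
    )


def estimate_diffusion_table(
    trajectories: pd.DataFrame,
    dt: float,
    n_lags: int = DEFAULT_N_LAGS,
    min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
    id_col: str = "trajectory_id",
    coord_cols: tuple[str, str] = ("x_um", "y_um"),
    extra_cols: tuple[str, ...] = ("video_index",),
) -> pd.DataFrame:
    """Per-trajectory diffusion estimates for a linked detection table.

    Vectorizes the common case where all trajectories share one length.
    Carries through any ``extra_cols`` (first value per trajectory).
    """
    xcol, ycol = coord_cols
    rows = []
    for tid, traj in trajectories.groupby(id_col, sort=True):
        est = estimate_diffusion(
            traj[xcol].to_numpy(),
            traj[ycol].to_numpy(),
            dt,
            n_lags=n_lags,
            trajectory_id=int(tid),
            min_track_length=min_track_length,
        )
        if est is None:
            continue
        row = {
            "trajectory_id": est.trajectory_id,
            "d_hat": est.d_hat,
            "se_d": est.se_d,
            "n_points": est.n_points,
            "clamped": est.clamped,
        }
        for c in extra_cols:
            if c in traj.columns:
                row[c] = traj[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_diffusion_array(
    positions: np.ndarray, dt: float, n_lags: int = DEFAULT_N_LAGS
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized diffusion estimates for equal-length trajectories.

    ``positions`` has shape (n_traj, n_frames, 2).  Same estimator as
    :func:`estimate_diffusion` (through-origin weighted MSD fit over lags
    1..n_lags, negative slopes clamped to 0); returns (d_hat, se_d) arrays.
    """
    positions = np.asarray(positions, dtype=float)
    n_traj, n_frames, _ = positions.shape
    n_lags = min(n_lags, n_frames - 1)
    msds = np.empty((n_traj, n_lags))
    npairs = np.empty(n_lags)
    for lag in range(1, n_lags + 1):
        disp = positions[:, lag:, :] - positions[:, :-lag, :]
        msds[:, lag - 1] = np.mean(np.sum(disp**2, axis=2), axis=1)
        npairs[lag - 1] = n_frames - lag
    lags_t = np.arange(1, n_lags + 1) * dt
    w = npairs
    denom = np.sum(w * lags_t**2)
    slopes = (msds * (w * lags_t)).sum(axis=1) / denom
    resid = msds - slopes[:, None] * lags_t
    dof = max(n_lags - 1, 1)
    var_slope = (w * resid**2).sum(axis=1) / dof / denom
    d_hat = np.clip(slopes / 4.0, 0.0, None)
    se_d = np.sqrt(np.clip(var_slope, 0.0, None)) / 4.0
    return d_hat, se_d


def ensemble_msd_slope(
    positions: np.ndarray, dt: float, n_lags: int = DEFAULT_N_LAGS
) -> tuple[float, float]:
    """Ensemble-mean MSD slope over many equal-length trajectories.

    ``positions`` has shape (n_traj, n_frames, 2).  Returns (slope, SE of
    the slope) for a through-origin fit of the ensemble MSD vs lag time;
    the SE comes from the spread of per-trajectory slopes.
    """
    positions = np.asarray(positions, dtype=float)
    n_traj = positions.shape[0]
    slopes = np.empty(n_traj)
    for i in range(n_traj):
        msd, npairs = msd_per_lag(positions[i, :, 0], positions[i, :, 1], n_lags)
        ok = npairs > 0
        lags_t = np.arange(1, n_lags + 1)[ok] * dt
        slopes[i], _ = _fit_msd_slope(lags_t, msd[ok], npairs[ok].astype(float))
    return float(slopes.mean()), float(slopes.std(ddof=1) / np.sqrt(n_traj))
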