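"""Bound/free classification of trajectories by threshold diffusion
coefficient, and per-video binding-event counting.

A molecule whose fitted diffusion coefficient falls strictly below the
threshold is a bound probe-plasmid complex; at or above it, a free probe.
The threshold itself is calibrated per solution condition (crowded
solutions slow the free probes, so a crowded condition gets its own
threshold) by brute-force misclassification minimization between reference
bound and free samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .conditions import SolutionCondition

__all__ = [
    "ThresholdModel",
    "calibrate_threshold",
    "classify_trajectories",
    "count_binding",
]

LABEL_BOUND = "bound"
LABEL_FREE = "free"


class SeparabilityError(ValueError):
    """Bound and free reference populations cannot be separated."""


@dataclass(frozen=True)
class ThresholdModel:
    """Diffusion-coefficient threshold separating bound from free.

    Strict rule: ``d_hat < d_threshold`` -> bound; the boundary case
    ``d_hat == d_threshold`` is assigned free.
    """

    d_threshold: float
    method: Literal["fixed", "two_population"] = "fixed"
    calibration_condition: SolutionCondition | None = None

    def __post_init__(self) -> None:
        if self.d_threshold <= 0:
            raise ValueError("d_threshold must be positive")

    def is_bound(self, d_hat: np.ndarray | float) -> np.ndarray | bool:
        return np.asarray(d_hat) < self.d_threshold


def calibrate_threshold(
    d_bound_sample: np.ndarray | pd.Series,
    d_free_sample: np.ndarray | pd.Series,
    condition: SolutionCondition | None = None,
    grid_fraction: float = 0.01,
) -> ThresholdModel:
    """Calibrate a threshold from reference bound and free D samples.

    Grid search between the two sample medians (step = ``grid_fraction``
    of the inter-median range) for the threshold minimizing total
    misclassification (bound counted as bound when strictly below the
    candidate).  When a plateau of thresholds achieves the minimum, the
    plateau midpoint is returned.  Deterministic.

    Raises
    ------
    SeparabilityError
        If the samples are empty, their medians coincide, or the bound
        median is not below the free median.
    """
    db = np.asarray(d_bound_sample, dtype=float)
    df = np.asarray(d_free_sample, dtype=float)
    if db.size == 0 or df.size == 0:
        raise SeparabilityError("reference samples must be non-empty")
    med_b, med_f = np.median(db), np.median(df)
    if med_b >= med_f:
        raise SeparabilityError(
            "populations not separable: bound median "
            f"({med_b:g}) not below free median ({med_f:g})"
        )
    grid = np.linspace(med_b, med_f, int(round(1.0 / grid_fraction)) + 1)
    # misclassified: bound with d >= thr, free with d < thr
    errors = np.array(
        [np.count_nonzero(db >= thr) + np.count_nonzero(df < thr) for thr in grid]
    )
    best = errors.min()
    at_best = np.flatnonzero(errors == best)
    # midpoint of the (contiguous) optimal plateau
    thr = float(grid[at_best].mean())
    return ThresholdModel(
        d_threshold=thr, method="two_population", calibration_condition=condition
    )


def classify_trajectories(
    estimates: pd.DataFrame, model: ThresholdModel
) -> pd.DataFrame:
    """Label each diffusion estimate bound/free by the strict threshold rule.

    Returns the estimates table with a ``label`` column added.
    """
    out = estimates.copy()
    out["label"] = np.where(
        out["d_hat"].to_numpy() < model.d_threshold, LABEL_BOUND, LABEL_FREE
    )
    return out


def count_binding(
    labeled: pd.DataFrame,
    n_probes_declared: int | None = None,
    time_of_video=None,
    replicate: int | None = None,
) -> pd.DataFrame:
    """Count bound complexes per 100 probes in each video.

    Parameters
    ----------
    labeled : table with ``video_index`` and ``label`` columns.
    n_probes_declared : optional denominator override.  When fast free
        probes blur beyond detectability the detection-based denominator is
        biased; supplying the config-declared probe count per video uses
        that instead of the observed trajectory count.
    time_of_video : callable or mapping from video_index to time (s);
        defaults to the video index itself.
    replicate : optional replicate id copied onto every row.

    Videos with zero trajectories are skipped with a warning.
    """
    if "video_index" not in labeled.columns:
        raise ValueError("labeled table must carry video_index")
    rows = []
    for v, grp in labeled.groupby("video_index", sort=True):
        n_obs = len(grp)
        if n_obs == 0:  # pragma: no cover - groupby yields non-empty groups
            continue
        n_bound = int((grp["label"] == LABEL_BOUND).sum())
        denom = n_probes_declared if n_probes_declared else n_obs
        if denom <= 0:
            warnings.warn(f"video {v}: no probes observed; skipped", stacklevel=2)
            continue
        if callable(time_of_video):
            t = float(time_of_video(v))
        elif time_of_video is not None:
            t = float(time_of_video[v])
        else:
            t = float(v)
        row = {
            "video_index": int(v),
            "t_s": t,
            "bound_per_100": 100.0 * n_bound / denom,
            "n_probes": int(denom),
            "n_bound": n_bound,
        }
        if replicate is not None:
            row["replicate"] = replicate
        rows.append(row)
    if not rows:
        warnings.warn("no videos with observed probes", stacklevel=2)
    return pd.DataFrame(rows)
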