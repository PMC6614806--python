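"""Ground-truthed synthetic data generation.

Three generators with the statistical structure the analysis pipeline
assumes:

* :func:`simulate_trajectories` — two-species (fast free probe / slow bound
  complex) Brownian motion confined to cylindrical pits, with stochastic,
  irreversible conversion of free probes to bound complexes at unwound
  plasmid sites.  The ensemble-expected bound count follows the saturating
  exponential ``U0*(1-exp(-K t))`` that the kinetics module fits.
* :func:`render_video` — fluorescence image stacks from trajectories:
  motion-blurred Gaussian PSF, constant background, Poisson shot noise.
* :func:`simulate_gel_lane` — topoisomer gel-lane intensity profiles with a
  Gaussian envelope over integer linking-number bands.

Motion is simulated in the 2-D imaging plane; the pit depth (~6x smaller
than the diameter) is treated as fully projected.  All stochastic draws
come from one seeded generator, so identical seed + config gives
bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams
from .topo import TopoisomerDistribution

__all__ = [
    "PitGeometry",
    "AcquisitionSchedule",
    "SpeciesParams",
    "GroundTruth",
    "simulate_trajectories",
    "render_video",
    "render_all_videos",
    "simulate_gel_lane",
    "STATE_FREE",
    "STATE_BOUND",
]

STATE_FREE = "free"
STATE_BOUND = "bound"

#: Gap-time criterion for equilibration inside a pit: when the per-axis
#: step variance 2*D*dt exceeds this multiple of R^2, the position is
#: redrawn from the uniform stationary distribution instead of stepped.
_MIXING_FACTOR = 10.0


@dataclass(frozen=True)
class PitGeometry:
    """Cylindrical nanopit array geometry (lengths in um)."""

    diameter: float = 3.0
    depth: float = 0.5
    pitch: float = 5.0
    n_pits: int = 4

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.depth <= 0:
            raise ValueError("diameter and depth must be positive")
        if self.pitch < self.diameter:
            raise ValueError("pitch must be >= diameter")
        if self.n_pits < 1:
            raise ValueError("n_pits must be >= 1")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def grid_shape(self) -> tuple[int, int]:
        cols = int(math.ceil(math.sqrt(self.n_pits)))
        rows = int(math.ceil(self.n_pits / cols))
        return rows, cols

    def pit_centers(self) -> np.ndarray:
        """(n_pits, 2) array of pit-center coordinates in um."""
        rows, cols = self.grid_shape()
        centers = []
        for i in range(self.n_pits):
            r, c = divmod(i, cols)
            centers.append(((c + 0.5) * self.pitch, (r + 0.5) * self.pitch))
        return np.asarray(centers)

    def field_extent(self) -> tuple[float, float]:
        """(width, height) of the imaged field in um."""
        rows, cols = self.grid_shape()
        return cols * self.pitch, rows * self.pitch


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Video acquisition timing (seconds).

    A *video* is a burst of ``frames_per_video`` frames spaced by
    ``intra_video_interval``; videos start every ``video_interval`` over
    ``total_duration``.  Defaults follow the 50 ms exposure / one video per
    minute / ~2 h observation pattern, with 100 frames per burst.
    """

    exposure: float = 0.05
    frames_per_video: int = 100
    intra_video_interval: float = 0.05
    video_interval: float = 60.0
    total_duration: float = 7200.0

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.intra_video_interval < self.exposure:
            raise ValueError("intra_video_interval must be >= exposure")
        if self.video_interval < self.frames_per_video * self.intra_video_interval:
            raise ValueError("video_interval shorter than one video burst")
        if self.total_duration < self.video_interval:
            raise ValueError("total_duration must cover at least one video")

    @property
    def n_videos(self) -> int:
        return int(self.total_duration // self.video_interval)

    def video_start_times(self) -> np.ndarray:
        return np.arange(self.n_videos) * self.video_interval

    def frame_times(self, video_index: int) -> np.ndarray:
        t0 = video_index * self.video_interval
        return t0 + np.arange(self.frames_per_video) * self.intra_video_interval


@dataclass(frozen=True)
class SpeciesParams:
    """Diffusion, stoichiometry, and photophysics of the simulated species.

    The default diffusion coefficients (20 vs 1 um^2/s) make the free and
    bound populations cleanly separable at 50 ms sampling; they are
    engineering defaults, overridable in config.
    """

    d_free: float = 20.0
    d_bound: float = 1.0
    n_probes_per_pit: int = 20
    n_plasmids_per_pit: int = 10
    photons_per_frame: float = 500.0
    background_photons: float = 10.0
    psf_sigma: float = 0.15
    pixel_size: float = 0.1
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.d_free > self.d_bound >= 0):
            raise ValueError("require d_free > d_bound >= 0")
        if self.n_probes_per_pit < 0 or self.n_plasmids_per_pit < 0:
            raise ValueError("counts must be non-negative")
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("psf_sigma and pixel_size must be positive")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")


@dataclass
class GroundTruth:
    """Generator-side truth for a simulated experiment."""

    params: KineticParams
    binding_times: dict[int, float]
    n_probes: int
    n_unwound_sites: int
    pit_of_molecule: np.ndarray
    seed: int

    def state_at(self, molecule_id: int, t: float) -> str:
        tb = self.binding_times.get(molecule_id, math.inf)
        return STATE_BOUND if t >= tb else STATE_FREE

    def expected_bound_per_100(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.params.bound_at(t)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _reflect_disc(pos: np.ndarray, radius: float) -> None:
    """Radial fold of out-of-disc positions back inside, in place.

    |r| -> 2R - |r| repeated until inside; preserves the uniform stationary
    distribution and guarantees no trajectory exits the disc.
    """
    for _ in range(64):
        r = np.hypot(pos[:, 0], pos[:, 1])
        out = r > radius
        if not out.any():
            return
        scale = (2.0 * radius - r[out]) / r[out]
        # a very deep overshoot can fold past the centre; clamp magnitude
        np.clip(scale, -1.0, 1.0, out=scale)
        pos[out] *= np.abs(scale)[:, None]
    # pathological step size: resample would break determinism; project
    r = np.hypot(pos[:, 0], pos[:, 1])
    out = r > radius
    pos[out] *= (radius / r[out])[:, None]


def _advance(
    pos: np.ndarray,
    d_coef: np.ndarray,
    dt: float,
    radius: float | None,
    rng: np.random.Generator,
) -> None:
    """Advance positions by one Brownian interval of length dt, in place.

    ``radius`` None means unconfined (pure Gaussian step).  In the confined
    case, molecules whose step variance exceeds the mixing criterion are
    redrawn from the uniform stationary distribution; the rest take a
    Gaussian step followed by specular (radial-fold) reflection.
    """
    if dt <= 0:
        return
    n = len(pos)
    var = 2.0 * d_coef * dt
    if radius is None:
        pos += rng.normal(size=(n, 2)) * np.sqrt(var)[:, None]
        return
    mixed = var > _MIXING_FACTOR * radius**2
    steps = rng.normal(size=(n, 2)) * np.sqrt(var)[:, None]
    uniform = _uniform_disc(rng, n, radius)
    pos += np.where(mixed[:, None], 0.0, steps)
    pos[mixed] = uniform[mixed]
    _reflect_disc(pos, radius)


def _draw_binding_schedule(
    geom: PitGeometry,
    sp: SpeciesParams,
    kin: KineticParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Assign exponential binding times to probes.

    Each plasmid is unwound independently with probability chosen so the
    expected number of open sites per pit is ``U0/100 * n_probes_per_pit``.
    Each open site draws a binding time ~ Exp(K) (probe pool treated as
    constant, the excess-probe limit) and captures one uniformly chosen
    still-free probe in its pit.  Returns per-probe binding times (inf for
    never-bound) and the realized number of unwound sites.
    """
    n_pits = geom.n_pits
    n_probes = n_pits * sp.n_probes_per_pit
    times = np.full(n_probes, np.inf)
    if kin.U0 == 0 or sp.n_plasmids_per_pit == 0 or sp.n_probes_per_pit == 0:
        return times, 0
    expected_sites = kin.U0 / 100.0 * sp.n_probes_per_pit
    p_unwound = expected_sites / sp.n_plasmids_per_pit
    if p_unwound > 1.0:
        raise ValueError(
            "not enough plasmids per pit to realize U0: "
            f"need p_unwound={p_unwound:.3f} <= 1"
        )
    total_sites = 0
    for pit in range(n_pits):
        n_open = rng.binomial(sp.n_plasmids_per_pit, p_unwound)
        total_sites += n_open
        if n_open == 0:
            continue
        site_times = np.sort(rng.exponential(1.0 / kin.K, size=n_open)) if kin.K > 0 else np.full(n_open, np.inf)
        probe_ids = pit * sp.n_probes_per_pit + np.arange(sp.n_probes_per_pit)
        free = list(probe_ids)
        for t_bind in site_times:
            if not free or not np.isfinite(t_bind):
                if not free:
                    warnings.warn(
                        f"pit {pit}: more open sites than probes; site unbound",
                        stacklevel=2,
                    )
                continue
            pick = int(rng.integers(len(free)))
            times[free.pop(pick)] = t_bind
    return times, total_sites


def simulate_trajectories(
    geom: PitGeometry,
    sched: AcquisitionSchedule,
    sp: SpeciesParams,
    kin: KineticParams,
    seed: int,
    confined: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate pit-confined probe trajectories with stochastic binding.

    Returns
    -------
    trajectories : DataFrame
        Columns ``molecule_id, video_index, frame, t_s, x_um, y_um, pit_id,
        state``; coordinates are global field coordinates in um.
    truth : GroundTruth
        Per-probe binding times and the generator kinetic parameters.

    Notes
    -----
    Free probes step with per-axis variance ``2*d_free*dt``; a probe
    captured by an open site at time ``t_b`` diffuses with ``d_bound`` for
    all t >= t_b (binding is irreversible; with U0 = 0 no binding occurs).
    Between video bursts, molecules that would fully equilibrate in the pit
    are redrawn from the uniform stationary distribution.
    """
    if kin.U0 > kin.P0:
        raise ValueError("U0 must not exceed P0")
    rng = np.random.default_rng(seed)
    radius = geom.radius if confined else None

    n_probes = geom.n_pits * sp.n_probes_per_pit
    pit_of = np.repeat(np.arange(geom.n_pits), sp.n_probes_per_pit)
    centers = geom.pit_centers()

    bind_times, n_sites = _draw_binding_schedule(geom, sp, kin, rng)

    if confined:
        pos = _uniform_disc(rng, n_probes, radius)
    else:
        pos = np.zeros((n_probes, 2))

    records_x = []
    records_y = []
    records_state = []
    frame_time_list = []
    video_list = []
    frame_list = []

    t_now = 0.0
    d_of = np.where(bind_times <= 0.0, sp.d_bound, sp.d_free)
    for v in range(sched.n_videos):
        t_video = v * sched.video_interval
        # inter-burst gap (from end of previous burst to start of this one)
        gap = t_video - t_now
        if gap > 0:
            newly = (bind_times > t_now) & (bind_times <= t_video)
            # split the gap at each molecule's binding time is overkill for
            # gaps >> mixing time; step once with the pre-binding D, then
            # switch.  (Both species fully mix over default 1-min gaps.)
            _advance(pos, d_of, gap, radius, rng)
            d_of[newly] = sp.d_bound
            t_now = t_video
        for f in range(sched.frames_per_video):
            t_frame = t_video + f * sched.intra_video_interval
            if f > 0:
                newly = (bind_times > t_now) & (bind_times <= t_frame)
                _advance(pos, d_of, t_frame - t_now, radius, rng)
                d_of[newly] = sp.d_bound
                t_now = t_frame
            bound_now = bind_times <= t_frame
            records_x.append(pos[:, 0] + (centers[pit_of, 0] if confined else 0.0))
            records_y.append(pos[:, 1] + (centers[pit_of, 1] if confined else 0.0))
            records_state.append(bound_now.copy())
            frame_time_list.append(np.full(n_probes, t_frame))
            video_list.append(np.full(n_probes, v, dtype=int))
            frame_list.append(np.full(n_probes, f, dtype=int))

    n_rows = len(records_x)
    mol_ids = np.tile(np.arange(n_probes), n_rows)
    df = pd.DataFrame(
        {
            "molecule_id": mol_ids,
            "video_index": np.concatenate(video_list),
            "frame": np.concatenate(frame_list),
            "t_s": np.concatenate(frame_time_list),
            "x_um": np.concatenate(records_x),
            "y_um": np.concatenate(records_y),
            "pit_id": np.tile(pit_of, n_rows),
            "state": np.where(
                np.concatenate(records_state), STATE_BOUND, STATE_FREE
            ),
        }
    )
    df.sort_values(["molecule_id", "video_index", "frame"], inplace=True, kind="stable")
    df.reset_index(drop=True, inplace=True)
    truth = GroundTruth(
        params=kin,
        binding_times={
            int(i): float(t) for i, t in enumerate(bind_times) if np.isfinite(t)
        },
        n_probes=n_probes,
        n_unwound_sites=n_sites,
        pit_of_molecule=pit_of,
        seed=seed,
    )
    return df, truth


def simulate_population(
    n_molecules: int,
    n_frames: int,
    dt: float,
    d_coef: float,
    seed: int,
    radius: float | None = None,
) -> np.ndarray:
    """Single-species Brownian trajectories as a (n_mol, n_frames, 2) array.

    ``radius`` None gives unconfined motion starting at the origin;
    otherwise motion is confined to a disc of that radius with uniform
    initial positions.  Used for threshold calibration references and for
    simulator-fidelity checks.
    """
    rng = np.random.default_rng(seed)
    d_arr = np.full(n_molecules, float(d_coef))
    if radius is None:
        pos = np.zeros((n_molecules, 2))
    else:
        pos = _uniform_disc(rng, n_molecules, radius)
    out = np.empty((n_molecules, n_frames, 2))
    out[:, 0] = pos
    for f in range(1, n_frames):
        _advance(pos, d_arr, dt, radius, rng)
        out[:, f] = pos
    return out


def _stamp_emitters(
    frame: np.ndarray,
    xs_px: np.ndarray,
    ys_px: np.ndarray,
    photons: float,
    sigma_px: float,
) -> None:
    """Add symmetric Gaussian spots (integral = photons) to a frame."""
    half = max(int(math.ceil(4.0 * sigma_px)), 2)
    ny, nx = frame.shape
    for x, y in zip(xs_px, ys_px):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, nx)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1)
        gy = np.arange(y0, y1)
        ex = np.exp(-0.5 * ((gx - x) / sigma_px) ** 2)
        ey = np.exp(-0.5 * ((gy - y) / sigma_px) ** 2)
        frame[y0:y1, x0:x1] += (
            photons / (2.0 * np.pi * sigma_px**2) * np.outer(ey, ex)
        )


def render_video(
    trajectories: pd.DataFrame,
    geom: PitGeometry,
    sp: SpeciesParams,
    sched: AcquisitionSchedule,
    video_index: int,
    seed: int,
    n_substeps: int = 8,
    noise: bool = True,
) -> np.ndarray:
    """Render one video burst as a uint16 image stack (frames, y, x).

    Each frame integrates the emitters over the exposure: ``n_substeps``
    intermediate positions are drawn by forward Brownian sub-stepping from
    the recorded frame position (motion blur), each carrying an equal share
    of the photon budget, convolved with a Gaussian PSF.  Constant
    background plus Poisson shot noise unless ``noise=False``.
    """
    rng = np.random.default_rng(seed)
    width, height = geom.field_extent()
    nx = int(round(width / sp.pixel_size))
    ny = int(round(height / sp.pixel_size))
    stack = np.empty((sched.frames_per_video, ny, nx), dtype=np.uint16)
    sub_dt = sched.exposure / n_substeps
    sigma_px = sp.psf_sigma / sp.pixel_size
    centers = geom.pit_centers()

    vid = trajectories[trajectories["video_index"] == video_index]
    by_frame = dict(tuple(vid.groupby("frame")))
    for f in range(sched.frames_per_video):
        img = np.full((ny, nx), float(sp.background_photons))
        rows = by_frame.get(f)
        if rows is not None and len(rows):
            x = rows["x_um"].to_numpy(dtype=float)
            y = rows["y_um"].to_numpy(dtype=float)
            d_coef = np.where(
                rows["state"].to_numpy() == STATE_BOUND, sp.d_bound, sp.d_free
            )
            pit = rows["pit_id"].to_numpy(dtype=int)
            # local pit coordinates so blur sub-steps respect confinement
            local = np.column_stack([x, y]) - centers[pit]
            photons_per_sub = sp.photons_per_frame / n_substeps
            for _ in range(n_substeps):
                gx = (local[:, 0] + centers[pit, 0]) / sp.pixel_size
                gy = (local[:, 1] + centers[pit, 1]) / sp.pixel_size
                _stamp_emitters(img, gx, gy, photons_per_sub, sigma_px)
                if n_substeps > 1:
                    _advance(local, d_coef, sub_dt, geom.radius, rng)
        if noise:
            img = rng.poisson(img).astype(float)
        stack[f] = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(
            np.uint16
        )
    return stack


def render_all_videos(
    trajectories: pd.DataFrame,
    geom: PitGeometry,
    sp: SpeciesParams,
    sched: AcquisitionSchedule,
    seed: int,
    **kwargs,
) -> list[np.ndarray]:
    """Render every video burst; per-video seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(sched.n_videos)
    return [
        render_video(
            trajectories,
            geom,
            sp,
            sched,
            video_index=v,
            seed=int(child_seeds[v].generate_state(1)[0]),
            **kwargs,
        )
        for v in range(sched.n_videos)
    ]


def simulate_gel_lane(
    dist: TopoisomerDistribution,
    noise_sd: float,
    seed: int,
    band_sigma: float = 0.15,
    band_spacing: float = 1.0,
    samples_per_band: int = 40,
    n_sd: float = 4.0,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Synthesize a 1-D gel-lane intensity profile for a topoisomer ladder.

    Bands sit at integer linking offsets (migration position =
    ``dlk * band_spacing``), each a narrow Gaussian peak of width
    ``band_sigma`` whose amplitude follows the distribution's Gaussian
    envelope; additive white noise of standard deviation ``noise_sd``
    (same units as the unit-peak envelope).

    Returns the profile as a (position, intensity) DataFrame plus the
    band-position map consumed by the envelope fitter.
    """
    rng = np.random.default_rng(seed)
    dlks = dist.band_grid(n_sd=n_sd)
    amps = np.asarray(dist.envelope(dlks.astype(float)))
    centers = dlks * band_spacing
    pad = 3.0 * band_sigma + band_spacing
    position = np.linspace(
        centers.min() - pad,
        centers.max() + pad,
        int(samples_per_band * (len(dlks) + 2)),
    )
    intensity = np.zeros_like(position)
    for c, a in zip(centers, amps):
        intensity += a * np.exp(-0.5 * ((position - c) / band_sigma) ** 2)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(position))
    profile = pd.DataFrame({"position": position, "intensity": intensity})
    band_positions = {int(d): float(c) for d, c in zip(dlks, centers)}
    return profile, band_positions
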