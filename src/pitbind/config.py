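"""Run configuration: YAML schema, validation, and hashing.

Schema (all keys optional unless noted; units in key names)::

    seed: 1                      # required for any stochastic stage
    mode: trajectories           # or "videos" (render + detect + link)
    n_replicates: 10
    condition:
      nacl_mM: 137.5
      tris_mM: 12.0
      hepes_mM: 25.0
      ph: 8.0
      temperature_c: 37.0
      crowder: {species: PEG, mw_da: 8000, conc_wv_pct: 10.0}
    geometry: {diameter_um: 3.0, depth_um: 0.5, pitch_um: 5.0, n_pits: 4}
    schedule:
      exposure_s: 0.05
      frames_per_video: 100
      intra_video_interval_s: 0.05
      video_interval_s: 60.0
      total_duration_s: 7200.0
    species:
      d_free_um2_s: 20.0
      d_bound_um2_s: 1.0
      n_probes_per_pit: 20
      n_plasmids_per_pit: 10
      photons_per_frame: 500
      background_photons: 10
      psf_sigma_um: 0.15
      pixel_size_um: 0.1
    kinetics: {P0: 100.0, U0: 10.0, K: 5.0e-4}   # generator truth
    analysis:
      n_lags: 4
      min_track_length: 10
      max_disp_um: 2.0
      max_gap: 1
      denominator: declared      # or "observed"
      n_reference: 200           # threshold-calibration sample size
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conditions import BufferModel, Crowder, CrowderSpecies, SolutionCondition
from .kinetics import KineticParams
from .synth import AcquisitionSchedule, PitGeometry, SpeciesParams

__all__ = ["AnalysisParams", "RunConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tracking/classification/fitting knobs shared across stages."""

    n_lags: int = 4
    min_track_length: int = 10
    max_disp_um: float = 2.0
    max_gap: int = 1
    denominator: str = "declared"
    n_reference: int = 200

    def __post_init__(self) -> None:
        if self.denominator not in ("declared", "observed"):
            raise ValueError("denominator must be 'declared' or 'observed'")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one synthetic experiment."""

    seed: int
    condition: SolutionCondition = field(default_factory=SolutionCondition)
    geometry: PitGeometry = field(default_factory=PitGeometry)
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    species: SpeciesParams = field(default_factory=SpeciesParams)
    kinetics: KineticParams = field(
        default_factory=lambda: KineticParams(P0=100.0, U0=10.0, K=5e-4)
    )
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    mode: str = "trajectories"
    n_replicates: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("trajectories", "videos"):
            raise ValueError("mode must be 'trajectories' or 'videos'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_dict(self) -> dict:
        c = self.condition
        crow = c.crowder
        return {
            "seed": self.seed,
            "mode": self.mode,
            "n_replicates": self.n_replicates,
            "condition": {
                "nacl_mM": c.nacl_conc,
                "tris_mM": c.buffer.tris_conc,
                "hepes_mM": c.buffer.hepes_conc,
                "ph": c.buffer.ph,
                "buffer_ionic_mM": c.buffer.ionic_contribution,
                "temperature_c": c.temperature,
                "crowder": {
                    "species": crow.species.value,
                    "mw_da": crow.molecular_weight,
                    "conc_wv_pct": crow.conc_wv,
                },
            },
            "geometry": {
                "diameter_um": self.geometry.diameter,
                "depth_um": self.geometry.depth,
                "pitch_um": self.geometry.pitch,
                "n_pits": self.geometry.n_pits,
            },
            "schedule": {
                "exposure_s": self.schedule.exposure,
                "frames_per_video": self.schedule.frames_per_video,
                "intra_video_interval_s": self.schedule.intra_video_interval,
                "video_interval_s": self.schedule.video_interval,
                "total_duration_s": self.schedule.total_duration,
            },
            "species": {
                "d_free_um2_s": self.species.d_free,
                "d_bound_um2_s": self.species.d_bound,
                "n_probes_per_pit": self.species.n_probes_per_pit,
                "n_plasmids_per_pit": self.species.n_plasmids_per_pit,
                "photons_per_frame": self.species.photons_per_frame,
                "background_photons": self.species.background_photons,
                "psf_sigma_um": self.species.psf_sigma,
                "pixel_size_um": self.species.pixel_size,
            },
            "kinetics": {
                "P0": self.kinetics.P0,
                "U0": self.kinetics.U0,
                "K": self.kinetics.K,
            },
            "analysis": {
                "n_lags": self.analysis.n_lags,
                "min_track_length": self.analysis.min_track_length,
                "max_disp_um": self.analysis.max_disp_um,
                "max_gap": self.analysis.max_gap,
                "denominator": self.analysis.denominator,
                "n_reference": self.analysis.n_reference,
            },
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("config must declare a seed")
        cond_d = d.get("condition", {})
        crow_d = cond_d.get("crowder") or {}
        species_name = crow_d.get("species", "none")
        if species_name == "none" or not crow_d:
            crowder = Crowder.none()
        else:
            crowder = Crowder(
                species=CrowderSpecies(species_name),
                molecular_weight=float(crow_d.get("mw_da", 0.0)),
                conc_wv=float(crow_d.get("conc_wv_pct", 0.0)),
                specific_excluded_volume=crow_d.get("specific_excluded_volume"),
                n_monomers=crow_d.get("n_monomers"),
            )
        buffer = BufferModel(
            tris_conc=float(cond_d.get("tris_mM", 12.0)),
            hepes_conc=float(cond_d.get("hepes_mM", 25.0)),
            ph=float(cond_d.get("ph", 8.0)),
            ionic_contribution=cond_d.get("buffer_ionic_mM"),
        )
        condition = SolutionCondition(
            nacl_conc=float(cond_d.get("nacl_mM", 0.0)),
            buffer=buffer,
            crowder=crowder,
            temperature=float(cond_d.get("temperature_c", 37.0)),
        )
        g = d.get("geometry", {})
        geometry = PitGeometry(
            diameter=float(g.get("diameter_um", 3.0)),
            depth=float(g.get("depth_um", 0.5)),
            pitch=float(g.get("pitch_um", 5.0)),
            n_pits=int(g.get("n_pits", 4)),
        )
        s = d.get("schedule", {})
        schedule = AcquisitionSchedule(
            exposure=float(s.get("exposure_s", 0.05)),
            frames_per_video=int(s.get("frames_per_video", 100)),
            intra_video_interval=float(s.get("intra_video_interval_s", 0.05)),
            video_interval=float(s.get("video_interval_s", 60.0)),
            total_duration=float(s.get("total_duration_s", 7200.0)),
        )
        sp = d.get("species", {})
        species = SpeciesParams(
            d_free=float(sp.get("d_free_um2_s", 20.0)),
            d_bound=float(sp.get("d_bound_um2_s", 1.0)),
            n_probes_per_pit=int(sp.get("n_probes_per_pit", 20)),
            n_plasmids_per_pit=int(sp.get("n_plasmids_per_pit", 10)),
            photons_per_frame=float(sp.get("photons_per_frame", 500.0)),
            background_photons=float(sp.get("background_photons", 10.0)),
            psf_sigma=float(sp.get("psf_sigma_um", 0.15)),
            pixel_size=float(sp.get("pixel_size_um", 0.1)),
        )
        k = d.get("kinetics", {})
        obs_rate = float(k["K"]) if "K" in k else None
        rate_const = float(k["k"]) if "k" in k else None
        if obs_rate is None and rate_const is None:
            obs_rate = 5e-4
        kinetics = KineticParams(
            P0=float(k.get("P0", 100.0)),
            U0=float(k.get("U0", 10.0)),
            K=obs_rate,
            k=rate_const,
        )
        a = d.get("analysis", {})
        analysis = AnalysisParams(
            n_lags=int(a.get("n_lags", 4)),
            min_track_length=int(a.get("min_track_length", 10)),
            max_disp_um=float(a.get("max_disp_um", 2.0)),
            max_gap=int(a.get("max_gap", 1)),
            denominator=str(a.get("denominator", "declared")),
            n_reference=int(a.get("n_reference", 200)),
        )
        return cls(
            seed=int(d["seed"]),
            condition=condition,
            geometry=geometry,
            schedule=schedule,
            species=species,
            kinetics=kinetics,
            analysis=analysis,
            mode=str(d.get("mode", "trajectories")),
            n_replicates=int(d.get("n_replicates", 10)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    return RunConfig.from_yaml(path)
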