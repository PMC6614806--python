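"""Topoisomer distributions: linking-number/superhelical-density conversions
and Gaussian-envelope fitting of gel-lane band intensities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DEFAULT_HELICAL_REPEAT_BP",
    "TopoisomerDistribution",
    "sigma_from_dlk",
    "dlk_from_sigma",
    "fit_band_distribution",
    "integrate_bands",
]

#: Standard B-DNA helical repeat, bp per turn.
DEFAULT_HELICAL_REPEAT_BP = 10.5


class EnvelopeError(ValueError):
    """Gaussian band envelope cannot be fitted."""


@dataclass
class TopoisomerDistribution:
    """Gaussian distribution of superhelical densities over topoisomers.

    Topoisomers differ by integer linking-number offsets ``dlk`` from the
    relaxed state; the envelope over band intensities is Gaussian in sigma
    with mean ``mean_sigma`` and standard deviation ``sd_sigma``.
    """

    plasmid_length: int
    mean_sigma: float
    sd_sigma: float
    helical_repeat: float = DEFAULT_HELICAL_REPEAT_BP
    band_intensities: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plasmid_length <= 0:
            raise ValueError("plasmid_length must be positive")
        if self.sd_sigma <= 0:
            raise ValueError("sd_sigma must be positive")
        if any(v < 0 for v in self.band_intensities.values()):
            raise ValueError("band intensities must be non-negative")

    @property
    def lk0(self) -> float:
        """Relaxed linking number, plasmid_length / helical_repeat."""
        return self.plasmid_length / self.helical_repeat

    def envelope(self, dlk: np.ndarray | float) -> np.ndarray | float:
        """Unnormalized Gaussian envelope intensity at linking offset dlk."""
        sigma = sigma_from_dlk(dlk, self.plasmid_length, self.helical_repeat)
        z = (sigma - self.mean_sigma) / self.sd_sigma
        return np.exp(-0.5 * np.asarray(z) ** 2)

    def band_grid(self, n_sd: float = 4.0) -> np.ndarray:
        """Integer dlk positions covering mean +/- n_sd envelope widths."""
        center = dlk_from_sigma(self.mean_sigma, self.plasmid_length, self.helical_repeat)
        half = self.sd_sigma * self.lk0 * n_sd
        lo = int(np.floor(center - half))
        hi = int(np.ceil(center + half))
        return np.arange(lo, hi + 1)


def sigma_from_dlk(
    dlk: np.ndarray | float,
    plasmid_length: int,
    helical_repeat: float = DEFAULT_HELICAL_REPEAT_BP,
) -> np.ndarray | float:
    """Superhelical density sigma = dlk / Lk0 with Lk0 = length/repeat."""
    if plasmid_length <= 0:
        raise ValueError("plasmid_length must be positive")
    lk0 = plasmid_length / helical_repeat
    return dlk / lk0


def dlk_from_sigma(
    sigma: np.ndarray | float,
    plasmid_length: int,
    helical_repeat: float = DEFAULT_HELICAL_REPEAT_BP,
) -> np.ndarray | float:
    """Inverse of :func:`sigma_from_dlk` (dlk need not be an integer)."""
    if plasmid_length <= 0:
        raise ValueError("plasmid_length must be positive")
    return sigma * (plasmid_length / helical_repeat)


def integrate_bands(
    position: np.ndarray,
    intensity: np.ndarray,
    band_centers: np.ndarray,
    window: float,
    baseline: str = "linear",
) -> np.ndarray:
    """Integrate lane intensity in a +/- window/2 region around each band.

    A local baseline — the straight line through the profile values at the
    two window edges (``baseline='linear'``) or zero (``'none'``) — is
    subtracted before integrating.  Negative integrals clip to zero.
    """
    position = np.asarray(position, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    areas = np.empty(len(band_centers))
    for i, c in enumerate(band_centers):
        mask = np.abs(position - c) <= window / 2.0
        if not mask.any():
            areas[i] = 0.0
            continue
        x, y = position[mask], intensity[mask]
        if baseline == "linear" and len(x) > 1:
            base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
            y = y - base
        areas[i] = max(np.trapezoid(y, x), 0.0)
    return areas


def fit_band_distribution(
    profile: pd.DataFrame | tuple[np.ndarray, np.ndarray],
    band_positions: dict[int, float],
    plasmid_length: int,
    helical_repeat: float = DEFAULT_HELICAL_REPEAT_BP,
    band_window: float | None = None,
    baseline: str = "linear",
) -> TopoisomerDistribution:
    """Fit a Gaussian envelope to topoisomer band intensities in a gel lane.

    Parameters
    ----------
    profile : DataFrame with columns (position, intensity), or a pair of arrays.
    band_positions : mapping from linking offset dlk to migration position.
        The gel-mobility calibration is the caller's responsibility.
    band_window : integration window around each band; defaults to 80% of
        the smallest spacing between adjacent bands.

    Returns
    -------
    TopoisomerDistribution with fitted ``mean_sigma``/``sd_sigma`` and the
    per-band integrated intensities.

    Raises
    ------
    EnvelopeError if fewer than three bands are supplied or the weighted
    least-squares Gaussian fit fails.
    """
    if isinstance(profile, pd.DataFrame):
        position = profile.iloc[:, 0].to_numpy(dtype=float)
        intensity = profile.iloc[:, 1].to_numpy(dtype=float)
    else:
        position, intensity = (np.asarray(a, dtype=float) for a in profile)
    if len(band_positions) < 3:
        raise EnvelopeError("envelope not identifiable: need >= 3 bands")

    dlks = np.array(sorted(band_positions), dtype=float)
    centers = np.array([band_positions[int(d)] for d in dlks])
    if band_window is None:
        spacing = np.min(np.abs(np.diff(np.sort(centers))))
        band_window = 0.8 * spacing
    areas = integrate_bands(position, intensity, centers, band_window, baseline)
    if np.count_nonzero(areas) < 3:
        raise EnvelopeError("envelope not identifiable: < 3 non-empty bands")

    def gauss(d, amp, mu, sd):
        return amp * np.exp(-0.5 * ((d - mu) / sd) ** 2)

    amp0 = float(areas.max())
    mu0 = float(np.sum(dlks * areas) / np.sum(areas))
    sd0 = float(np.sqrt(np.sum(areas * (dlks - mu0) ** 2) / np.sum(areas))) or 1.0
    try:
        popt, _ = curve_fit(
            gauss,
            dlks,
            areas,
            p0=(amp0, mu0, sd0),
            bounds=([0.0, dlks.min() - 5, 1e-6], [np.inf, dlks.max() + 5, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise EnvelopeError(f"Gaussian envelope fit failed: {exc}") from exc
    _, mu, sd = popt

    mean_sigma = float(sigma_from_dlk(mu, plasmid_length, helical_repeat))
    sd_sigma = float(abs(sigma_from_dlk(sd, plasmid_length, helical_repeat)))
    return TopoisomerDistribution(
        plasmid_length=plasmid_length,
        mean_sigma=mean_sigma,
        sd_sigma=sd_sigma,
        helical_repeat=helical_repeat,
        band_intensities={int(d): float(a) for d, a in zip(dlks, areas)},
    )
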