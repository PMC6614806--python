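"""Solution-condition bookkeeping: ionic strength and crowder excluded volume.

Unit conventions used throughout the package:

===================  =========================================
quantity             unit
===================  =========================================
ionic strength       mM (millimolar)
salt/buffer conc.    mM
crowder conc.        % w/v  (grams of polymer per 100 mL)
excluded volume      % v/v  (mL excluded per 100 mL solution)
specific excl. vol.  mL per gram of polymer
temperature          degrees Celsius
===================  =========================================

The buffer ionic contribution is a *calibrated* quantity, not a
Henderson-Hasselbalch computation: for the reference composition
(12 mM Tris + 25 mM HEPES at pH 8.0) the partially ionized buffers
together contribute 12.5 mM.  An optional Henderson-Hasselbalch
estimate is provided for exploration but is never used by default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "CrowderSpecies",
    "BufferModel",
    "Crowder",
    "SolutionCondition",
    "total_ionic_strength",
    "excluded_volume_fraction",
    "crossover_concentration",
    "PEG8K_SPECIFIC_EXCLUDED_VOLUME_ML_PER_G",
    "REFERENCE_BUFFER_IONIC_CONTRIBUTION_MM",
]

#: mL of solution volume excluded per gram of 8 kDa PEG.  Calibrated so that
#: 1% w/v of 8 kDa PEG excludes 1.31% v/v; the same constant reproduces the
#: full (w/v -> v/v) series 5% -> 6.55%, 10% -> 13.1%, 20% -> 26.2%.
PEG8K_SPECIFIC_EXCLUDED_VOLUME_ML_PER_G = 1.31

#: Combined ionized-species contribution (mM) of 12 mM Tris + 25 mM HEPES
#: at pH 8.0.  Calibration constant; see module docstring.
REFERENCE_BUFFER_IONIC_CONTRIBUTION_MM = 12.5

_REFERENCE_TRIS_MM = 12.0
_REFERENCE_HEPES_MM = 25.0
_REFERENCE_PH = 8.0

# Standard 25 C pKa values, used only by the optional Henderson-Hasselbalch
# estimate (which does NOT reproduce the calibrated 12.5 mM).
_TRIS_PKA = 8.07
_HEPES_PKA = 7.48


class CrowderSpecies(str, enum.Enum):
    """Inert crowding polymer identity."""

    PEG = "PEG"
    PVP = "PVP"
    NONE = "none"


class ConditionError(ValueError):
    """Invalid solution-condition parameter."""


@dataclass(frozen=True)
class BufferModel:
    """Tris/HEPES buffer composition and its calibrated ionic contribution.

    Parameters
    ----------
    tris_conc, hepes_conc : float
        Buffer concentrations in mM.
    ph : float
        Solution pH.
    ionic_contribution : float
        Total contribution of dissociated buffer species to the ionic
        strength, in mM.  Defaults to the calibrated reference value when
        the composition matches the reference buffer.
    """

    tris_conc: float = _REFERENCE_TRIS_MM
    hepes_conc: float = _REFERENCE_HEPES_MM
    ph: float = _REFERENCE_PH
    ionic_contribution: float | None = None

    def __post_init__(self) -> None:
        if self.tris_conc < 0 or self.hepes_conc < 0:
            raise ConditionError("buffer concentrations must be non-negative")
        if self.ionic_contribution is None:
            if self._is_reference_composition():
                object.__setattr__(
                    self, "ionic_contribution", REFERENCE_BUFFER_IONIC_CONTRIBUTION_MM
                )
            else:
                raise ConditionError(
                    "ionic_contribution must be given explicitly for "
                    "non-reference buffer compositions (no calibration exists)"
                )
        if self.ionic_contribution < 0:
            raise ConditionError("ionic_contribution must be non-negative")

    def _is_reference_composition(self) -> bool:
        return (
            math.isclose(self.tris_conc, _REFERENCE_TRIS_MM)
            and math.isclose(self.hepes_conc, _REFERENCE_HEPES_MM)
            and math.isclose(self.ph, _REFERENCE_PH)
        )

    @classmethod
    def reference(cls) -> "BufferModel":
        """The reference buffer: 12 mM Tris, 25 mM HEPES, pH 8.0 -> 12.5 mM."""
        return cls()

    def henderson_hasselbalch_contribution(self) -> float:
        """Ionized-fraction estimate of the buffer contribution (mM).

        Exploratory only: sums ``c * f_ionized`` for Tris (cationic acid
        form below its pKa) and HEPES (anionic base form above its pKa)
        using standard pKa values.  Not the calibrated value and never used
        in ionic-strength accounting by default.
        """
        tris_ionized = self.tris_conc / (1.0 + 10.0 ** (self.ph - _TRIS_PKA))
        hepes_ionized = self.hepes_conc / (1.0 + 10.0 ** (_HEPES_PKA - self.ph))
        return tris_ionized + hepes_ionized


@dataclass(frozen=True)
class Crowder:
    """An inert crowding polymer at a given mass/volume concentration.

    ``specific_excluded_volume`` (mL/g) converts % w/v to % v/v excluded
    volume; the packaged calibration covers 8 kDa PEG.  ``n_monomers`` is
    the degree of polymerization used by the semidilute crossover estimate
    and must be supplied by the caller when that estimate is wanted.
    """

    species: CrowderSpecies = CrowderSpecies.NONE
    molecular_weight: float = 0.0
    conc_wv: float = 0.0
    specific_excluded_volume: float | None = None
    n_monomers: float | None = None

    def __post_init__(self) -> None:
        if self.conc_wv < 0:
            raise ConditionError("conc_wv must be non-negative")
        if self.species is not CrowderSpecies.NONE:
            if self.molecular_weight <= 0:
                raise ConditionError("molecular_weight must be positive")
            if self.specific_excluded_volume is None and self._is_peg8k():
                object.__setattr__(
                    self,
                    "specific_excluded_volume",
                    PEG8K_SPECIFIC_EXCLUDED_VOLUME_ML_PER_G,
                )
            if self.specific_excluded_volume is None:
                raise ConditionError(
                    "specific_excluded_volume must be given for crowders "
                    "other than 8 kDa PEG (no calibration exists)"
                )
            if self.specific_excluded_volume <= 0:
                raise ConditionError("specific_excluded_volume must be positive")
            if self.n_monomers is not None and self.n_monomers < 1:
                raise ConditionError("n_monomers must be >= 1")

    def _is_peg8k(self) -> bool:
        return self.species is CrowderSpecies.PEG and math.isclose(
            self.molecular_weight, 8000.0, rel_tol=0.05
        )

    @classmethod
    def none(cls) -> "Crowder":
        return cls(species=CrowderSpecies.NONE)

    @classmethod
    def peg8k(cls, conc_wv: float, n_monomers: float | None = None) -> "Crowder":
        """8 kDa PEG at ``conc_wv`` % w/v with the packaged calibration."""
        return cls(
            species=CrowderSpecies.PEG,
            molecular_weight=8000.0,
            conc_wv=conc_wv,
            n_monomers=n_monomers,
        )


@dataclass(frozen=True)
class SolutionCondition:
    """Complete solution condition: salt, buffer, crowder, temperature."""

    nacl_conc: float = 0.0
    buffer: BufferModel = field(default_factory=BufferModel.reference)
    crowder: Crowder = field(default_factory=Crowder.none)
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.nacl_conc < 0:
            raise ConditionError("nacl_conc must be non-negative")
        if not (0.0 < self.temperature < 100.0):
            raise ConditionError("temperature must be in (0, 100) C")

    @property
    def ionic_strength(self) -> float:
        return total_ionic_strength(self)

    @property
    def excluded_volume(self) -> float:
        return excluded_volume_fraction(self.crowder)

    def label(self) -> str:
        parts = [f"{self.ionic_strength:g} mM"]
        if self.crowder.species is not CrowderSpecies.NONE:
            parts.append(
                f"{self.crowder.conc_wv:g}% w/v "
                f"{self.crowder.molecular_weight / 1000:g} kDa "
                f"{self.crowder.species.value}"
            )
        return ", ".join(parts)


def total_ionic_strength(cond: SolutionCondition) -> float:
    """Total ionic strength (mM): NaCl (fully dissociated) plus the
    calibrated buffer contribution.

    NaCl dissociates completely at pH 8.0; Tris and HEPES contribute only
    their ionized fractions, which the :class:`BufferModel` carries as a
    calibrated constant.
    """
    return cond.nacl_conc + cond.buffer.ionic_contribution


def excluded_volume_fraction(crowder: Crowder) -> float:
    """Excluded-volume fraction (% v/v) of a crowder solution.

    Linear in concentration: ``conc_wv`` is g per 100 mL, so the excluded
    volume is ``conc_wv * specific_excluded_volume`` mL per 100 mL, i.e.
    the % v/v value equals the product directly.
    """
    if crowder.species is CrowderSpecies.NONE or crowder.conc_wv == 0.0:
        return 0.0
    return crowder.conc_wv * crowder.specific_excluded_volume


def crossover_concentration(crowder: Crowder) -> float:
    """Semidilute crossover concentration c* = N^(-4/5), as % w/v.

    ``N`` (degree of polymerization) is a caller-supplied parameter of the
    :class:`Crowder`; the Flory scaling makes no claim about how N should
    be computed from molecular weight.
    """
    n = crowder.n_monomers
    if n is None:
        raise ConditionError("crossover_concentration requires n_monomers")
    if n < 1:
        raise ConditionError("n_monomers must be >= 1")
    return 100.0 * n ** (-0.8)
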