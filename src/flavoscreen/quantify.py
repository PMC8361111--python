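"""pH-differential quantification of monomeric anthocyanins.

The flavylium cation absorbs strongly near 520 nm at pH 1.0 and converts
to the colorless hemiketal at pH 4.5; the absorbance difference between
the two buffers, corrected for haze at 700 nm, is proportional to the
monomeric anthocyanin concentration:

    A = (A520 - A700)_pH1.0 - (A520 - A700)_pH4.5

Concentrations are read off a linear standard curve of the differential
absorbance of cyanin (cyanidin 3,5-diglucoside) and converted to mg of
cyanin equivalents per g of tissue via the extract volume, the tissue mass
and the standard's molar mass.  A dilution identity (c1*V1 = c2*V2)
corrects for water carried into the extraction solvent by fresh tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AbsorbanceSet",
    "StandardCurve",
    "DilutionSpec",
    "QuantResult",
    "CYANIN_CATION_MOLAR_MASS",
    "differential_absorbance",
    "fit_standard_curve",
    "dilution_correct",
    "yield_mg_per_g",
    "quantify_sample",
]

logger = logging.getLogger(__name__)

#: Molar mass (g/mol) of the cyanin flavylium cation (cyanidin 3,5-diglucoside,
#: C27H31O16+).  The chloride salt would be ~35.5 g/mol heavier; the cation
#: basis is the default because the pigment in solution is the cation.
CYANIN_CATION_MOLAR_MASS = 611.16


@dataclass(frozen=True)
class AbsorbanceSet:
    """Paired 520/700 nm readings at pH 1.0 and pH 4.5 for one replicate."""

    a520_ph1: float
    a700_ph1: float
    a520_ph45: float
    a700_ph45: float
    replicate: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        for name in ("a520_ph1", "a700_ph1", "a520_ph45", "a700_ph45"):
            if getattr(self, name) < 0:
                raise ValueError(f"absorbance {name} must be >= 0")


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of differential absorbance (AU) on concentration (uM)."""

    concentrations: tuple[float, ...]
    differential_absorbances: tuple[float, ...]
    slope: float  # AU per uM
    intercept: float  # AU
    r_squared: float

    def inverse(self, absorbance: float) -> float:
        """Concentration (uM) whose fitted absorbance equals ``absorbance``."""
        if self.slope == 0:
            raise ZeroDivisionError("standard curve has zero slope")
        return (absorbance - self.intercept) / self.slope


@dataclass(frozen=True)
class DilutionSpec:
    """c1*V1 = c2*V2: rescale a measured concentration to a reference volume."""

    c1: float
    v1: float
    v2: float

    def __post_init__(self) -> None:
        if min(self.c1, self.v1, self.v2) <= 0:
            raise ValueError("concentration and volumes must be positive")


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one sample in cyanin equivalents."""

    differential_absorbance: float
    concentration_uM: float
    yield_dw: float  # mg per g dry weight
    yield_fw: float | None  # mg per g fresh weight, when water content known
    standard: str
    standard_molar_mass: float


def differential_absorbance(readings: AbsorbanceSet) -> float:
    """(A520 - A700) at pH 1.0 minus the same difference at pH 4.5.

    May be negative for blank-like or mis-ordered readings; such values are
    logged and passed through unchanged.
    """
    a = (readings.a520_ph1 - readings.a700_ph1) - (readings.a520_ph45 - readings.a700_ph45)
    if a < 0:
        logger.warning(
            "negative differential absorbance %.4f for sample %r replicate %r "
            "(blank or swapped buffers?)",
            a,
            readings.sample,
            readings.replicate,
        )
    return a


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of absorbance on concentration, with intercept."""
    if len(points) < 2:
        raise ValueError("need at least 2 standard points")
    conc = np.array([p[0] for p in points], dtype=float)
    au = np.array([p[1] for p in points], dtype=float)
    if np.allclose(conc, conc[0]):
        raise ValueError("all standard concentrations identical: singular fit")
    if len(points) == 2:
        slope = (au[1] - au[0]) / (conc[1] - conc[0])
        intercept = au[0] - slope * conc[0]
        r2 = 1.0
    else:
        fit = stats.linregress(conc, au)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return StandardCurve(tuple(conc), tuple(au), slope, intercept, r2)


def dilution_correct(spec: DilutionSpec) -> float:
    """c2 = c1 * V1 / V2."""
    return spec.c1 * spec.v1 / spec.v2


def yield_mg_per_g(
    absorbance: float,
    curve: StandardCurve,
    extract_volume_l: float,
    tissue_mass_g: float,
    standard_molar_mass: float = CYANIN_CATION_MOLAR_MASS,
) -> float:
    """Pigment yield in mg standard-equivalents per g tissue.

    Inverse regression gives the molar concentration (uM) in the extract;
    times the extract volume gives mol of pigment, times the molar mass
    gives mg, divided by the tissue mass gives mg/g.
    """
    if extract_volume_l <= 0 or tissue_mass_g <= 0 or standard_molar_mass <= 0:
        raise ValueError("volume, mass and molar mass must be positive")
    conc_um = curve.inverse(absorbance)
    mg = conc_um * 1e-6 * extract_volume_l * standard_molar_mass * 1e3
    return mg / tissue_mass_g


def quantify_sample(
    readings: AbsorbanceSet,
    curve: StandardCurve,
    extract_volume_l: float,
    tissue_mass_g: float,
    standard_molar_mass: float = CYANIN_CATION_MOLAR_MASS,
    water_content: float | None = None,
    standard: str = "cyanin",
) -> QuantResult:
    """Full pH-differential quantification of one replicate.

    ``water_content`` is the fresh-tissue water fraction in [0, 1); when
    given, the fresh-weight yield is the dry-weight yield scaled by the dry
    matter fraction (1 - water_content).
    """
    a = differential_absorbance(readings)
    conc = curve.inverse(a)
    dw = yield_mg_per_g(a, curve, extract_volume_l, tissue_mass_g, standard_molar_mass)
    fw = None
    if water_content is not None:
        if not 0 <= water_content < 1:
            raise ValueError("water_content must lie in [0, 1)")
        fw = dw * (1 - water_content)
    return QuantResult(
        differential_absorbance=a,
        concentration_uM=conc,
        yield_dw=dw,
        yield_fw=fw,
        standard=standard,
        standard_molar_mass=standard_molar_mass,
    )
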