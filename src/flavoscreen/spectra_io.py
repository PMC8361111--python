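"""MGF spectrum I/O and the in-memory spectrum model.

All downstream stages consume the :class:`Spectrum` container defined here.
Reading and writing of Mascot Generic Format files goes through
:mod:`pyteomics.mgf`; this module adds the domain conventions on top:
retention times are converted from the MGF's RTINSECONDS to minutes (the
unit of the annotation library), a missing CHARGE line defaults to 1+
(positive-mode flavylium cations are singly charged), and malformed blocks
are rejected with a logged warning rather than aborting the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["FragmentPeak", "Spectrum", "read_mgf", "write_mgf", "filter_fragments"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class FragmentPeak:
    """One MS/MS product ion: m/z (Th) and intensity (arbitrary counts)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"fragment m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"fragment intensity must be >= 0, got {self.intensity}")


def _canonical_fragments(fragments: Iterable[FragmentPeak]) -> tuple[FragmentPeak, ...]:
    # sort ascending by m/z; duplicate m/z values collapse to the most intense peak
    best: dict[float, FragmentPeak] = {}
    for f in fragments:
        if f.mz not in best or f.intensity > best[f.mz].intensity:
            best[f.mz] = f
    return tuple(best[mz] for mz in sorted(best))


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS peak: precursor, charge, retention time and product ions.

    Fragments are stored sorted strictly ascending by m/z with duplicate m/z
    values deduplicated (most intense kept). ``rt`` is in minutes.
    """

    id: str
    precursor_mz: float
    charge: int = 1
    rt: float = 0.0
    fragments: tuple[FragmentPeak, ...] = ()
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"spectrum {self.id!r}: precursor m/z must be positive")
        if self.charge < 1:
            raise ValueError(f"spectrum {self.id!r}: charge must be >= 1")
        if self.rt < 0:
            raise ValueError(f"spectrum {self.id!r}: retention time must be >= 0")
        object.__setattr__(self, "fragments", _canonical_fragments(self.fragments))

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([f.mz for f in self.fragments])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([f.intensity for f in self.fragments])


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into :class:`Spectrum` objects.

    One spectrum per BEGIN IONS block.  A block without PEPMASS is rejected
    with a warning; a missing CHARGE defaults to 1+ and the number of such
    defaults is logged.  RTINSECONDS is converted to minutes.

    Raises ``OSError`` if the file cannot be read at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MGF file not found: {path}")
    spectra: list[Spectrum] = []
    n_rejected = 0
    n_charge_defaulted = 0
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                n_rejected += 1
                logger.warning("rejecting MGF block %d (%s): no PEPMASS", i, title)
                continue
            charge_field = params.get("charge")
            if charge_field:
                charge = abs(int(charge_field[0]))
            else:
                charge = 1
                n_charge_defaulted += 1
            rt_seconds = float(params.get("rtinseconds", 0.0))
            fragments = tuple(
                FragmentPeak(float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                Spectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=max(charge, 1),
                    rt=rt_seconds / 60.0,
                    fragments=fragments,
                    sample=str(params.get("sample", "")),
                )
            )
    if n_rejected:
        logger.warning("%s: rejected %d malformed block(s)", path.name, n_rejected)
    if n_charge_defaulted:
        logger.info(
            "%s: defaulted CHARGE to 1+ for %d spectrum(s)", path.name, n_charge_defaulted
        )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Serialize spectra to MGF with deterministic field order.

    m/z values are written with 5 decimal places, intensities with 1; the
    read/write pair round-trips any valid spectrum list to that precision.
    """
    path = Path(path)
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "charge": s.charge,
                    "rtinseconds": s.rt * 60.0,
                    "sample": s.sample,
                },
            }
        )
    with path.open("w") as fh:
        _mgf.write(
            entries,
            fh,
            key_order=["title", "pepmass", "charge", "rtinseconds", "sample"],
            fragment_format="{:.5f} {:.1f}",
        )


def filter_fragments(spectrum: Spectrum, min_intensity: float) -> Spectrum:
    """Copy of ``spectrum`` keeping only fragments with intensity >= ``min_intensity``.

    The boundary is kept: the removal rule is "abundance below the floor is
    removed", so a fragment exactly at the floor survives.  Idempotent and
    monotone in the floor.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    kept = tuple(f for f in spectrum.fragments if f.intensity >= min_intensity)
    return replace(spectrum, fragments=kept)
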