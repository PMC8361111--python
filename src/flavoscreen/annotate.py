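"""Library matching and structural classification of screened spectra.

The bundled library transcribes the 18 high-confidence sweet-potato
anthocyanins (16 chromatographic peaks, two of them carrying co-eluting
pairs) with their observed precursor m/z, aglycone and qualifying fragment
ions, average retention times and block compositions.  Matching follows a
level-2 evidence standard: precursor mass agreement, presence of the
aglycone signature fragment, and at least one qualifying fragment; the
retention-time gate is optional because RTs shift between chromatographic
setups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .mass_model import BuildingBlock, Composition, cation_mz, default_blocks
from .spectra_io import Spectrum

__all__ = [
    "LibraryEntry",
    "AnnotationRecord",
    "load_library",
    "match",
    "classify_acylation",
    "classify_aglycone",
    "write_annotations",
]

logger = logging.getLogger(__name__)

#: Max allowed gap between a composed cation mass and the library's observed
#: precursor m/z.  The instrument's average mass error is ~0.002 Da but the
#: printed observed values deviate from theory by up to ~0.011 Da, so the
#: load-time consistency check uses 0.015 Da.
LIBRARY_MASS_TOLERANCE = 0.015


@dataclass(frozen=True)
class LibraryEntry:
    """One library anthocyanin: identity, evidence ions and composition."""

    peak_no: str
    name: str
    ygm_alias: str | None
    acylation_class: str  # {"Non", "Mono", "Di"}
    rt: float  # minutes
    precursor_mz: float
    aglycone_mzs: tuple[float, ...]
    qualifying_mzs: tuple[float, ...]
    composition: Composition
    ambiguous_core: tuple[str, ...] = ()  # candidate cores when MS/MS shows more than one


@dataclass(frozen=True)
class AnnotationRecord:
    """Outcome of matching one spectrum against the library."""

    spectrum_id: str
    entry: LibraryEntry | None
    precursor_error: float | None  # Da, observed - library
    matched_fragments: int
    rt_error: float | None  # minutes, None when the RT gate is off


def _bundled_library_path():
    return resources.files("flavoscreen.data") / "anthocyanin_library.tsv"


def load_library(
    path: str | Path | None = None,
    blocks: Mapping[str, BuildingBlock] | None = None,
) -> list[LibraryEntry]:
    """Load and validate the anthocyanin library TSV.

    Each row's composition is re-composed and checked against the recorded
    precursor m/z (within ``LIBRARY_MASS_TOLERANCE``), and the acylation
    class must equal the acyl count.  Any violation is a fatal error naming
    the row.  The bundled library yields 18 entries.
    """
    table = dict(blocks) if blocks is not None else default_blocks()
    if path is None:
        with resources.as_file(_bundled_library_path()) as p:
            text = Path(p).read_text()
        origin = "bundled library"
    else:
        text = Path(path).read_text()
        origin = str(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{origin}: library file is empty")
    header = lines[0].split("\t")
    entries: list[LibraryEntry] = []
    class_by_count = {0: "Non", 1: "Mono", 2: "Di"}
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        peak = row["peak_no"]
        core_field = row["core"]
        cores = core_field.split("|")
        try:
            composition = Composition(
                core=table[cores[0]],
                glycosyls=tuple(table[g] for g in row["glycosyls"].split(";") if g),
                acyls=tuple(table[a] for a in row.get("acyls", "").split(";") if a),
            )
        except KeyError as exc:
            raise ValueError(f"{origin}: peak {peak}: unknown building block {exc}") from exc
        entry = LibraryEntry(
            peak_no=peak,
            name=row["name"],
            ygm_alias=row["ygm_alias"] or None,
            acylation_class=row["acylation_class"],
            rt=float(row["rt_min"]),
            precursor_mz=float(row["precursor_mz"]),
            aglycone_mzs=tuple(float(x) for x in row["aglycone_mzs"].split(";")),
            qualifying_mzs=tuple(float(x) for x in row["qualifying_mzs"].split(";")),
            composition=composition,
            ambiguous_core=tuple(cores) if len(cores) > 1 else (),
        )
        err = cation_mz(composition) - entry.precursor_mz
        if abs(err) > LIBRARY_MASS_TOLERANCE:
            raise ValueError(
                f"{origin}: peak {peak}: composed cation m/z {cation_mz(composition):.4f} "
                f"deviates {err:+.4f} Da from recorded precursor {entry.precursor_mz}"
            )
        expected_class = class_by_count.get(len(composition.acyls), "Poly")
        if entry.acylation_class != expected_class:
            raise ValueError(
                f"{origin}: peak {peak}: acylation class {entry.acylation_class!r} "
                f"inconsistent with {len(composition.acyls)} acyl group(s)"
            )
        entries.append(entry)
    return entries


def match(
    spectrum: Spectrum,
    library: Sequence[LibraryEntry],
    mz_tol: float = 0.01,
    rt_tol: float | None = None,
    strict: bool = False,
) -> AnnotationRecord:
    """Best library match for a spectrum, or an empty record if none passes.

    An entry is eligible when the precursor agrees within ``mz_tol``, at
    least one aglycone fragment is present, and at least one qualifying
    fragment is present (all of them when ``strict``).  When ``rt_tol`` is
    given, the spectrum's RT must also fall within it.  Candidates are
    ranked by matched-fragment count (desc), then absolute precursor error,
    then RT error, then library order.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    frag_mzs = spectrum.mz_array
    candidates: list[tuple[tuple, AnnotationRecord]] = []
    for idx, entry in enumerate(library):
        prec_err = spectrum.precursor_mz - entry.precursor_mz
        if abs(prec_err) > mz_tol:
            continue
        rt_err = None
        if rt_tol is not None:
            rt_err = spectrum.rt - entry.rt
            if abs(rt_err) > rt_tol:
                continue
        if len(frag_mzs) == 0:
            continue
        n_agly = sum(
            1 for mz in entry.aglycone_mzs if (abs(frag_mzs - mz) <= mz_tol).any()
        )
        n_qual = sum(
            1 for mz in entry.qualifying_mzs if (abs(frag_mzs - mz) <= mz_tol).any()
        )
        if n_agly == 0 or n_qual == 0:
            continue
        if strict and n_qual < len(entry.qualifying_mzs):
            continue
        record = AnnotationRecord(
            spectrum_id=spectrum.id,
            entry=entry,
            precursor_error=prec_err,
            matched_fragments=n_agly + n_qual,
            rt_error=rt_err,
        )
        rank = (
            -record.matched_fragments,
            abs(prec_err),
            abs(rt_err) if rt_err is not None else math.inf,
            idx,
        )
        candidates.append((rank, record))
    if not candidates:
        return AnnotationRecord(spectrum.id, None, None, 0, None)
    return min(candidates, key=lambda c: c[0])[1]


def classify_acylation(composition: Composition) -> str:
    """Acylation class by acyl-residue count: Non (0), Mono (1), Di (2), Poly (>2)."""
    n = len(composition.acyls)
    return {0: "Non", 1: "Mono", 2: "Di"}.get(n, "Poly")


def classify_aglycone(
    spectrum: Spectrum,
    accurate_cores: Mapping[str, float] | None = None,
    mz_tol: float = 0.01,
    intensity_floor: float = 3000.0,
) -> tuple[str, ...]:
    """Anthocyanidin core(s) whose accurate cation mass appears among fragments.

    Returns the matching core names sorted by name: an empty tuple means no
    core fragment was found, a single name is an unambiguous call, and more
    than one name is an ambiguous call (both cores' signature fragments are
    present, as happens for co-fragmenting isobars).
    """
    if accurate_cores is None:
        accurate_cores = {
            b.name: b.monoisotopic_mass for b in default_blocks().values() if b.kind == "core"
        }
    found = []
    for name, mass in accurate_cores.items():
        for f in spectrum.fragments:
            if f.intensity >= intensity_floor and abs(f.mz - mass) <= mz_tol:
                found.append(name)
                break
    return tuple(sorted(found))


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records as a TSV (one row per spectrum)."""
    rows = []
    for r in records:
        rows.append(
            {
                "spectrum_id": r.spectrum_id,
                "peak_no": r.entry.peak_no if r.entry else "",
                "name": r.entry.name if r.entry else "",
                "ygm_alias": (r.entry.ygm_alias or "") if r.entry else "",
                "acylation_class": r.entry.acylation_class if r.entry else "",
                "precursor_error": r.precursor_error,
                "matched_fragments": r.matched_fragments,
                "rt_error": r.rt_error,
            }
        )
    cols = [
        "spectrum_id",
        "peak_no",
        "name",
        "ygm_alias",
        "acylation_class",
        "precursor_error",
        "matched_fragments",
        "rt_error",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
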