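"""Building-block mass tables and anthocyanin mass arithmetic.

Anthocyanins are detected in positive mode as intact flavylium cations
[M]+, so a composed monoisotopic mass *is* the expected m/z at charge 1.
A candidate anthocyanin is modelled as one anthocyanidin core (flavylium
cation) plus a multiset of glycosyl residues (sugar minus water) and acyl
residues (aromatic acid minus water).  This module owns the block tables,
forward composition (``cation_mz``), the diagnostic-fragment calculator
(``expected_fragments``) and the inverse search (``decompose``).
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BuildingBlock",
    "Composition",
    "ELECTRON_MASS",
    "MONOISOTOPIC_ELEMENT_MASSES",
    "cation_mz",
    "decompose",
    "default_blocks",
    "disaccharide_masses",
    "expected_fragments",
    "load_building_blocks",
    "mass_from_formula",
]

#: Monoisotopic masses of the elements occurring in flavonoid building blocks (Da).
MONOISOTOPIC_ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
}

#: Electron rest mass (Da); subtracted once for a singly charged cation.
ELECTRON_MASS = 0.00054858

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def mass_from_formula(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula like ``C15H11O6``."""
    mass = 0.0
    seen = False
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        seen = True
        try:
            mass += MONOISOTOPIC_ELEMENT_MASSES[element] * int(count or 1)
        except KeyError:
            raise ValueError(f"unsupported element {element!r} in formula {formula!r}")
    if not seen:
        raise ValueError(f"empty or unparseable formula {formula!r}")
    return mass


@dataclass(frozen=True)
class BuildingBlock:
    """A named mass unit: anthocyanidin core, glycosyl residue or acyl residue.

    Cores carry the flavylium *cation* mass (neutral formula minus one
    electron); glycosyl and acyl blocks carry residue masses (unit minus
    water), i.e. the mass they add when condensed onto the scaffold.
    """

    name: str
    kind: str  # {"core", "glycosyl", "acyl"}
    formula: str
    monoisotopic_mass: float
    nominal_mass: int

    def __post_init__(self) -> None:
        if self.kind not in {"core", "glycosyl", "acyl"}:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.nominal_mass != round(self.monoisotopic_mass):
            raise ValueError(
                f"block {self.name!r}: nominal mass {self.nominal_mass} does not "
                f"round from monoisotopic {self.monoisotopic_mass}"
            )


@dataclass(frozen=True)
class Composition:
    """One core plus multisets of glycosyl and acyl residues."""

    core: BuildingBlock
    glycosyls: tuple[BuildingBlock, ...] = ()
    acyls: tuple[BuildingBlock, ...] = ()

    def __post_init__(self) -> None:
        if self.core.kind != "core":
            raise ValueError(f"composition core must have kind 'core', got {self.core.kind!r}")
        for b in self.glycosyls:
            if b.kind != "glycosyl":
                raise ValueError(f"{b.name!r} is not a glycosyl block")
        for b in self.acyls:
            if b.kind != "acyl":
                raise ValueError(f"{b.name!r} is not an acyl block")
        # canonical order so equal multisets compare equal
        object.__setattr__(self, "glycosyls", tuple(sorted(self.glycosyls, key=lambda b: b.name)))
        object.__setattr__(self, "acyls", tuple(sorted(self.acyls, key=lambda b: b.name)))

    @property
    def n_blocks(self) -> int:
        return 1 + len(self.glycosyls) + len(self.acyls)

    def describe(self) -> str:
        parts = [self.core.name]
        for group in (self.glycosyls, self.acyls):
            for name, n in sorted(Counter(b.name for b in group).items()):
                parts.append(f"{n}x{name}" if n > 1 else name)
        return " + ".join(parts)


def load_building_blocks(path: str | Path) -> dict[str, BuildingBlock]:
    """Read a block table TSV (name, kind, formula, monoisotopic_mass, nominal_mass).

    The stored monoisotopic mass is cross-checked against the formula (cores
    as cations, residues as written) to within 1 mDa; a mismatch is a data
    error and raises.
    """
    blocks: dict[str, BuildingBlock] = {}
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["name", "kind", "formula", "monoisotopic_mass", "nominal_mass"]
    if header != expected:
        raise ValueError(f"building-block table header {header} != {expected}")
    for ln in lines[1:]:
        name, kind, formula, mono, nominal = ln.split("\t")
        block = BuildingBlock(name, kind, formula, float(mono), int(nominal))
        computed = mass_from_formula(formula)
        if kind == "core":
            computed -= ELECTRON_MASS
        if abs(computed - block.monoisotopic_mass) > 1e-3:
            raise ValueError(
                f"block {name!r}: stored mass {block.monoisotopic_mass} differs from "
                f"formula-derived {computed:.4f}"
            )
        # keep full precision internally; the TSV column is for human readers
        blocks[name] = BuildingBlock(name, kind, formula, computed, int(nominal))
    return blocks


def default_blocks() -> dict[str, BuildingBlock]:
    """The bundled block table: 8 anthocyanidin cores, 3 sugars, 3 acyl groups."""
    with resources.as_file(
        resources.files("flavoscreen.data") / "building_blocks.tsv"
    ) as p:
        return load_building_blocks(p)


def cation_mz(composition: Composition) -> float:
    """m/z of the intact flavylium cation [M]+ (charge 1) for a composition.

    Additive: core cation mass plus every glycosyl and acyl residue mass.
    """
    return (
        composition.core.monoisotopic_mass
        + sum(b.monoisotopic_mass for b in composition.glycosyls)
        + sum(b.monoisotopic_mass for b in composition.acyls)
    )


def expected_fragments(composition: Composition) -> list[float]:
    """The diagnostic evidence ions for an anthocyanin composition.

    Returns, deduplicated and ascending:

    * the bare aglycone cation (core) m/z,
    * the core + one glycosyl residue m/z for each distinct glycosyl, and
    * the precursor minus one glycosyl residue for each distinct glycosyl
      ([M - sugar]+, the dominant glycosidic-bond cleavage).

    With zero glycosyls only the core m/z is returned.
    """
    core_mz = composition.core.monoisotopic_mass
    out = {core_mz}
    precursor = cation_mz(composition)
    for sugar in {b.name: b for b in composition.glycosyls}.values():
        out.add(core_mz + sugar.monoisotopic_mass)
        out.add(precursor - sugar.monoisotopic_mass)
    return sorted(out)


def decompose(
    precursor_mz: float,
    tolerance: float = 0.01,
    blocks: Mapping[str, BuildingBlock] | None = None,
    max_glycosyls: int = 4,
    max_acyls: int = 3,
) -> list[Composition]:
    """All compositions whose cation m/z lies within ``tolerance`` of the precursor.

    Bounded exhaustive search over cores x glycosyl multisets (size 0..max_glycosyls)
    x acyl multisets (size 0..max_acyls).  Results are sorted by absolute mass
    error, then fewest blocks, then name, so the head of the list is the most
    parsimonious explanation.  The default 0.01 Da tolerance separates caffeoyl
    (162.0317) from hexose (162.0528) despite their shared nominal mass.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    table = dict(blocks) if blocks is not None else default_blocks()
    cores = [b for b in table.values() if b.kind == "core"]
    glycosyls = [b for b in table.values() if b.kind == "glycosyl"]
    acyls = [b for b in table.values() if b.kind == "acyl"]
    if not cores:
        raise ValueError("block table contains no core")
    if precursor_mz <= min(c.monoisotopic_mass for c in cores) - tolerance:
        return []

    def multisets(pool: Sequence[BuildingBlock], max_n: int) -> list[tuple[BuildingBlock, ...]]:
        out: list[tuple[BuildingBlock, ...]] = []
        for n in range(max_n + 1):
            out.extend(itertools.combinations_with_replacement(pool, n))
        return out

    acyl_sets = multisets(acyls, max_acyls)
    hits: list[Composition] = []
    for core in cores:
        for gly in multisets(glycosyls, max_glycosyls):
            base = core.monoisotopic_mass + sum(b.monoisotopic_mass for b in gly)
            if base > precursor_mz + tolerance:
                continue
            for acy in acyl_sets:
                total = base + sum(b.monoisotopic_mass for b in acy)
                if abs(total - precursor_mz) <= tolerance:
                    hits.append(Composition(core, gly, acy))
    hits.sort(
        key=lambda c: (abs(cation_mz(c) - precursor_mz), c.n_blocks, c.describe())
    )
    return hits


def disaccharide_masses(glycosyls: Iterable[BuildingBlock] | Iterable[int]) -> frozenset[int]:
    """Nominal disaccharide masses: pairwise sums (with repetition) of sugar nominals.

    Three monosaccharides (hexose 162, deoxyhexose 146, pentose 132) yield the
    six disaccharide values {324, 308, 294, 292, 278, 264}.
    """
    nominals = sorted(
        b.nominal_mass if isinstance(b, BuildingBlock) else int(b) for b in glycosyls
    )
    if not nominals:
        raise ValueError("need at least one glycosyl block")
    return frozenset(a + b for a, b in itertools.combinations_with_replacement(nominals, 2))
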