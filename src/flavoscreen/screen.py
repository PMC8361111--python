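"""Fragment co-occurrence screening and candidate filtering.

Implements the in-house discovery stage for anthocyanin-like peaks in
untargeted LC-MS/MS data:

* the **co-occurrence screen**: a spectrum is a candidate when it contains
  both an anthocyanidin aglycone fragment (nominal m/z bait) and the
  corresponding mono- or disaccharide derivative of that same aglycone,
  each with intensity at or above a floor;
* the **singly-charged filter** (flavylium cations carry one charge);
* the **mass-defect exclusion**: precursors whose after-decimal m/z falls
  in a window atypical of flavonoids are flagged as contaminants, unless
  rescued by independent evidence (e.g. surviving the co-occurrence screen);
* **classifier-score calibration**: the acceptance threshold for an external
  classifier's posterior scores is set to the minimum score achieved by a
  validated compound, and the filter then keeps everything at or above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .mass_model import default_blocks, disaccharide_masses
from .spectra_io import Spectrum

__all__ = [
    "ScreenConfig",
    "ScreenHit",
    "cooccurrence_screen",
    "mass_defect_filter",
    "calibrate_threshold",
    "score_filter",
    "read_score_table",
    "write_hits",
]

logger = logging.getLogger(__name__)

#: Nominal flavylium cation m/z of the eight anthocyanidin baits.
DEFAULT_AGLYCONE_NOMINALS = frozenset({271, 287, 301, 303, 315, 317, 331, 345})

#: Nominal residue masses of the three monosaccharides.
DEFAULT_MONO_NOMINALS = frozenset({162, 146, 132})


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the discovery screen.

    ``nominal_tolerance`` is the half-width used when matching accurate
    fragment m/z against integer nominal baits; 0.5 Da accepts any fragment
    whose nominal mass equals the bait.
    """

    intensity_floor: float = 3000.0
    nominal_tolerance: float = 0.5
    aglycone_nominals: frozenset[int] = DEFAULT_AGLYCONE_NOMINALS
    mono_nominals: frozenset[int] = DEFAULT_MONO_NOMINALS
    defect_window: tuple[float, float] = (0.40, 0.80)
    require_singly_charged: bool = True

    def __post_init__(self) -> None:
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if self.nominal_tolerance <= 0:
            raise ValueError("nominal_tolerance must be positive")
        lo, hi = self.defect_window
        if not (0 <= lo <= hi < 1):
            raise ValueError("defect_window must satisfy 0 <= lo <= hi < 1")

    @property
    def derivative_deltas(self) -> frozenset[int]:
        """Mono- plus disaccharide nominal residue masses."""
        return self.mono_nominals | disaccharide_masses(sorted(self.mono_nominals))


@dataclass(frozen=True)
class ScreenHit:
    """Evidence that a spectrum contains an aglycone and its glycoside derivative."""

    spectrum_id: str
    aglycone_nominal: int
    core_fragment_mz: float
    core_fragment_intensity: float
    derivative_fragment_mz: float
    derivative_fragment_intensity: float
    derivative_delta: int  # the mono/disaccharide nominal mass that matched


def cooccurrence_screen(
    spectra: Iterable[Spectrum], cfg: ScreenConfig = ScreenConfig()
) -> list[ScreenHit]:
    """Select spectra containing an anthocyanidin fragment and its glycoside.

    For every spectrum (restricted to charge 1 when configured) and every
    aglycone bait ``A``, a hit is emitted iff some fragment lies within
    ``nominal_tolerance`` of ``A`` and some fragment lies within the same
    tolerance of ``A + delta`` for a mono- or disaccharide residue ``delta``,
    both with intensity at or above the floor.  At most one hit per
    (spectrum, aglycone): the most intense derivative evidence wins, with the
    most intense core fragment.
    """
    deltas = sorted(cfg.derivative_deltas)
    hits: list[ScreenHit] = []
    for s in spectra:
        if cfg.require_singly_charged and s.charge != 1:
            continue
        strong = [f for f in s.fragments if f.intensity >= cfg.intensity_floor]
        if not strong:
            continue
        for aglycone in sorted(cfg.aglycone_nominals):
            cores = [f for f in strong if abs(f.mz - aglycone) <= cfg.nominal_tolerance]
            if not cores:
                continue
            best = None
            best_delta = None
            for delta in deltas:
                target = aglycone + delta
                for f in strong:
                    if abs(f.mz - target) <= cfg.nominal_tolerance:
                        if best is None or f.intensity > best.intensity:
                            best, best_delta = f, delta
            if best is None:
                continue
            core = max(cores, key=lambda f: f.intensity)
            hits.append(
                ScreenHit(
                    spectrum_id=s.id,
                    aglycone_nominal=aglycone,
                    core_fragment_mz=core.mz,
                    core_fragment_intensity=core.intensity,
                    derivative_fragment_mz=best.mz,
                    derivative_fragment_intensity=best.intensity,
                    derivative_delta=best_delta,
                )
            )
    return hits


def mass_defect_filter(
    spectra: Sequence[Spectrum],
    rescued_ids: set[str] = frozenset(),
    cfg: ScreenConfig = ScreenConfig(),
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Partition spectra into (kept, removed) by precursor after-decimal m/z.

    A precursor whose fractional m/z lies in the closed ``defect_window``
    (default [0.40, 0.80], atypical of flavonoids) is flagged and removed,
    unless its id is in ``rescued_ids`` (independent in-house evidence, e.g.
    a co-occurrence screen hit).  Everything else is kept unconditionally.
    """
    lo, hi = cfg.defect_window
    kept: list[Spectrum] = []
    removed: list[Spectrum] = []
    for s in spectra:
        # round to 6 dp so printed masses like 500.40 land exactly on the
        # closed window boundary despite float representation
        defect = round(s.precursor_mz % 1.0, 6)
        if lo <= defect <= hi and s.id not in rescued_ids:
            removed.append(s)
        else:
            kept.append(s)
    if removed:
        logger.info(
            "mass-defect filter removed %d spectrum(s); %d flagged-but-rescued",
            len(removed),
            sum(1 for s in kept if lo <= s.precursor_mz % 1.0 <= hi),
        )
    return kept, removed


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a classifier score TSV with columns (spectrum_id, class_label, posterior)."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    required = {"spectrum_id", "class_label", "posterior"}
    if missing := required - set(df.columns):
        raise ValueError(f"score table {path} missing column(s): {sorted(missing)}")
    if ((df["posterior"] < 0) | (df["posterior"] > 1)).any():
        raise ValueError("posterior scores must lie in [0, 1]")
    return df


def calibrate_threshold(
    scores: pd.DataFrame, validated_ids: set[str], class_label: str = "Flavonoid"
) -> float:
    """Minimum posterior over validated compounds for the target class.

    This is the most permissive threshold at which every independently
    validated compound is still accepted.  A validated id missing from the
    table (for the target class) is a fatal error naming the id.
    """
    sub = scores[scores["class_label"] == class_label]
    by_id = sub.groupby("spectrum_id")["posterior"].max()
    missing = sorted(set(validated_ids) - set(by_id.index))
    if missing:
        raise KeyError(f"validated id(s) absent from score table: {missing}")
    if not validated_ids:
        raise ValueError("validated_ids must be non-empty")
    return float(by_id.loc[sorted(validated_ids)].min())


def score_filter(
    scores: pd.DataFrame, threshold: float, class_label: str = "Flavonoid"
) -> set[str]:
    """Ids whose posterior for ``class_label`` is >= ``threshold``.

    The boundary is inclusive so the compound that set the calibration
    threshold passes its own filter.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    sub = scores[(scores["class_label"] == class_label) & (scores["posterior"] >= threshold)]
    return set(sub["spectrum_id"])


def write_hits(hits: Sequence[ScreenHit], path: str | Path) -> None:
    """Write screen hits as a TSV, one row per hit."""
    import dataclasses

    cols = [f.name for f in dataclasses.fields(ScreenHit)]
    pd.DataFrame([vars(h) for h in hits], columns=cols).to_csv(path, sep="\t", index=False)
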