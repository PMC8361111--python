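"""Seeded synthetic inputs for the whole pipeline.

Emulates the statistical structure the screen and filters assume, at desk
scale: MS/MS spectra for each library anthocyanin (evidence ions above the
intensity floor plus sub-floor noise), decoy spectra constructed to violate
the co-occurrence criterion, contaminant spectra with after-decimal
precursor m/z in the non-flavonoid window, classifier score tables around a
configured calibration minimum, spectrophotometric absorbance readings from
a known concentration and standard curve, and per-cultivar abundance
matrices.  Everything is driven by a single integer seed and is
byte-identical across runs with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import LibraryEntry, load_library
from .mass_model import default_blocks
from .screen import ScreenConfig
from .spectra_io import FragmentPeak, Spectrum, write_mgf

__all__ = [
    "SyntheticSpec",
    "generate_library_spectra",
    "generate_decoys",
    "generate_contaminants",
    "generate_scores",
    "generate_absorbances",
    "generate_abundances",
    "generate_demo_dataset",
]

DEFAULT_CULTIVARS = ("Kotobuki", "All Purple", "Purple Passion")


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic data generator.

    Evidence-fragment intensities are log-normal with median ten times the
    screen's intensity floor (clipped at the floor so embedded evidence is
    never lost to sampling noise); noise fragments sit strictly below the
    floor.  ``contaminant_fraction`` is the fraction of non-library spectra
    in the demo dataset given contaminant-style precursors (after-decimal
    m/z uniform in the defect window); half the contaminants are doubly
    charged to exercise the charge filter.
    """

    seed: int = 0
    n_decoys: int = 50
    n_noise_fragments: int = 5
    contaminant_fraction: float = 0.2
    intensity_floor: float = 3000.0
    intensity_median: float = 30000.0
    intensity_sigma: float = 0.5
    cultivar_labels: tuple[str, ...] = DEFAULT_CULTIVARS
    inclusion_probability: float = 1.0
    score_minimum: float = 0.63337

    def __post_init__(self) -> None:
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if not 0 <= self.inclusion_probability <= 1:
            raise ValueError("inclusion_probability must lie in [0, 1]")
        if not 0 <= self.score_minimum <= 1:
            raise ValueError("score_minimum must lie in [0, 1]")


def _evidence_intensity(rng: np.random.Generator, spec: SyntheticSpec) -> float:
    x = rng.lognormal(math.log(spec.intensity_median), spec.intensity_sigma)
    return float(max(x, spec.intensity_floor))


def _noise_fragments(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    upper_mz: float,
    avoid: Sequence[float] = (),
) -> list[FragmentPeak]:
    """Sub-floor noise peaks, rejection-sampled away from evidence ions."""
    out: list[FragmentPeak] = []
    while len(out) < spec.n_noise_fragments:
        mz = float(rng.uniform(150.0, max(upper_mz, 200.0)))
        if any(abs(mz - a) < 0.05 for a in avoid):
            continue
        intensity = float(rng.uniform(0.05, 0.95) * spec.intensity_floor)
        out.append(FragmentPeak(mz, intensity))
    return out


def generate_library_spectra(
    library: Sequence[LibraryEntry], spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[Spectrum]:
    """One spectrum per library entry with all evidence ions above the floor.

    Fragments are the entry's aglycone and qualifying ions at log-normal
    intensities plus seeded sub-floor noise; precursor and RT are the
    entry's recorded values.  Spectrum ids are ``lib_<peak_no>``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    spectra = []
    for entry in library:
        evidence = list(entry.aglycone_mzs) + list(entry.qualifying_mzs)
        frags = [FragmentPeak(mz, _evidence_intensity(rng, spec)) for mz in evidence]
        frags += _noise_fragments(rng, spec, entry.precursor_mz, avoid=evidence)
        spectra.append(
            Spectrum(
                id=f"lib_{entry.peak_no}",
                precursor_mz=entry.precursor_mz,
                charge=1,
                rt=entry.rt,
                fragments=tuple(frags),
                sample="pooled",
            )
        )
    return spectra


def _bait_targets(cfg: ScreenConfig) -> list[float]:
    targets = [float(a) for a in cfg.aglycone_nominals]
    targets += [float(a + d) for a in cfg.aglycone_nominals for d in cfg.derivative_deltas]
    return sorted(set(targets))


def _clear_of_baits(mz: float, targets: Sequence[float], margin: float) -> bool:
    return all(abs(mz - t) > margin for t in targets)


def _flavonoid_like_precursor(
    rng: np.random.Generator, library: Sequence[LibraryEntry]
) -> float:
    """Precursor with after-decimal in [0.05, 0.35], away from library masses."""
    lib_mzs = [e.precursor_mz for e in library]
    while True:
        mz = float(np.floor(rng.uniform(400, 1200)) + rng.uniform(0.05, 0.35))
        if all(abs(mz - x) > 0.05 for x in lib_mzs):
            return mz


def generate_decoys(
    spec: SyntheticSpec,
    n: int | None = None,
    cfg: ScreenConfig = ScreenConfig(),
    library: Sequence[LibraryEntry] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Spectrum]:
    """Negative-control spectra that can never pass the co-occurrence screen.

    Three families, cycled: (i) aglycone core fragment only, (ii) glycoside
    derivative fragment only, (iii) both present but below the intensity
    floor.  Families (i)/(ii) carry exactly one above-floor fragment, so no
    (core, derivative) pair at or above the floor can exist; family (iii)
    carries none.  Ids are ``decoy_<family>_<k>``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    n = spec.n_decoys if n is None else n
    library = library if library is not None else load_library()
    cores = {
        b.nominal_mass: b.monoisotopic_mass
        for b in default_blocks().values()
        if b.kind == "core" and b.nominal_mass in cfg.aglycone_nominals
    }
    nominals = sorted(cores)
    deltas = sorted(cfg.derivative_deltas)
    out: list[Spectrum] = []
    for k in range(n):
        family = ("core_only", "derivative_only", "subfloor")[k % 3]
        aglycone = nominals[k % len(nominals)]
        delta = deltas[k % len(deltas)]
        core_mz = cores[aglycone]
        deriv_mz = aglycone + delta + float(rng.uniform(-0.3, 0.3))
        if family == "core_only":
            evidence = [FragmentPeak(core_mz, _evidence_intensity(rng, spec))]
        elif family == "derivative_only":
            evidence = [FragmentPeak(deriv_mz, _evidence_intensity(rng, spec))]
        else:
            sub = lambda: float(rng.uniform(0.2, 0.9) * spec.intensity_floor)
            evidence = [FragmentPeak(core_mz, sub()), FragmentPeak(deriv_mz, sub())]
        precursor = _flavonoid_like_precursor(rng, library)
        frags = evidence + _noise_fragments(
            rng, spec, precursor, avoid=[f.mz for f in evidence]
        )
        out.append(
            Spectrum(
                id=f"decoy_{family}_{k}",
                precursor_mz=precursor,
                charge=1,
                rt=float(rng.uniform(0.5, 9.5)),
                fragments=tuple(frags),
                sample="pooled",
            )
        )
    return out


def generate_contaminants(
    spec: SyntheticSpec,
    n: int,
    cfg: ScreenConfig = ScreenConfig(),
    rng: np.random.Generator | None = None,
) -> list[Spectrum]:
    """Contaminant spectra: after-decimal precursor m/z inside the defect window.

    Above-floor fragments are rejection-sampled at least 0.6 Da away from
    every screen bait target, so contaminants can never hit the screen;
    every other one is doubly charged.  Ids are ``cont_<k>``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    lo, hi = cfg.defect_window
    targets = _bait_targets(cfg)
    out: list[Spectrum] = []
    for k in range(n):
        precursor = float(np.floor(rng.uniform(300, 1000)) + rng.uniform(lo, hi))
        frags: list[FragmentPeak] = []
        while len(frags) < 3:
            mz = float(rng.uniform(150.0, precursor))
            if _clear_of_baits(mz, targets, 0.6):
                frags.append(FragmentPeak(mz, _evidence_intensity(rng, spec)))
        frags += _noise_fragments(rng, spec, precursor, avoid=[f.mz for f in frags])
        out.append(
            Spectrum(
                id=f"cont_{k}",
                precursor_mz=precursor,
                charge=2 if k % 2 else 1,
                rt=float(rng.uniform(0.5, 9.5)),
                fragments=tuple(frags),
                sample="pooled",
            )
        )
    return out


def generate_scores(
    ids: Sequence[str],
    validated_ids: set[str],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    class_label: str = "Flavonoid",
) -> pd.DataFrame:
    """Posterior score table with a known calibration minimum.

    Validated ids receive scores in [score_minimum, 1], with the first
    (sorted) validated id pinned exactly at the minimum so calibration
    recovers it; other ids draw from a uniform mixture straddling the
    threshold.
    """
    if not set(validated_ids) <= set(ids):
        raise ValueError("validated_ids must be a subset of ids")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 3)
    validated_sorted = sorted(validated_ids)
    rows = []
    for sid in ids:
        if sid in validated_ids:
            if sid == validated_sorted[0]:
                score = spec.score_minimum
            else:
                score = float(rng.uniform(spec.score_minimum, 1.0))
        else:
            score = float(rng.uniform(0.0, 1.0))
        rows.append({"spectrum_id": sid, "class_label": class_label, "posterior": score})
    return pd.DataFrame(rows, columns=["spectrum_id", "class_label", "posterior"])


def generate_absorbances(
    true_conc: float,
    slope: float,
    intercept: float,
    noise_sd: float,
    n: int,
    rng: np.random.Generator | int = 0,
    sample: str = "sample",
) -> pd.DataFrame:
    """Replicate 520/700 nm readings whose differential follows the curve.

    The differential absorbance of each replicate is
    ``slope * true_conc + intercept + N(0, noise_sd)``; constant baseline
    and haze readings are added so all four raw channels are positive.
    Columns match the absorbance CSV schema
    (sample, replicate, a520_ph1, a700_ph1, a520_ph45, a700_ph45).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a700_ph1, a700_ph45, a520_ph45 = 0.020, 0.010, 0.100
    rows = []
    for i in range(n):
        diff = slope * true_conc + intercept + float(rng.normal(0.0, noise_sd))
        a520_ph1 = diff + (a520_ph45 - a700_ph45) + a700_ph1
        rows.append(
            {
                "sample": sample,
                "replicate": f"r{i + 1}",
                "a520_ph1": round(max(a520_ph1, 0.0), 6),
                "a700_ph1": a700_ph1,
                "a520_ph45": a520_ph45,
                "a700_ph45": a700_ph45,
            }
        )
    return pd.DataFrame(rows)


def generate_abundances(
    library: Sequence[LibraryEntry],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cultivar peak-area matrix for the library compounds.

    Areas are log-normal; each compound is present in each cultivar with
    ``inclusion_probability`` (absent means zero area).  Row ids match the
    synthetic spectrum ids (``lib_<peak_no>``).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 4)
    data = {}
    for cultivar in spec.cultivar_labels:
        col = []
        for entry in library:
            present = rng.uniform() < spec.inclusion_probability
            area = float(rng.lognormal(math.log(1e6), 1.0)) if present else 0.0
            col.append(area)
        data[cultivar] = col
    return pd.DataFrame(
        data, index=[f"lib_{e.peak_no}" for e in library], columns=list(spec.cultivar_labels)
    )


def generate_demo_dataset(
    outdir: str | Path,
    spec: SyntheticSpec = SyntheticSpec(),
    cfg: ScreenConfig = ScreenConfig(),
) -> dict[str, Path]:
    """Write a complete, seeded demo dataset and return its file paths.

    Produces ``spectra.mgf`` (library + decoys + contaminants), a
    classifier ``scores.tsv`` (library spectra validated), an
    ``absorbances.csv`` with four replicates per cultivar, and an
    ``abundances.csv`` peak-area matrix.  The contaminant count is
    ``round(contaminant_fraction / (1 - contaminant_fraction))`` of the
    library + decoy total, so contaminants make up ``contaminant_fraction``
    of the full cohort.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = load_library()
    rng = np.random.default_rng(spec.seed)
    lib_spectra = generate_library_spectra(library, spec, rng)
    decoys = generate_decoys(spec, cfg=cfg, library=library, rng=rng)
    n_cont = round(
        spec.contaminant_fraction / (1 - spec.contaminant_fraction)
        * (len(lib_spectra) + len(decoys))
    )
    contaminants = generate_contaminants(spec, n_cont, cfg=cfg, rng=rng)
    spectra = lib_spectra + decoys + contaminants
    paths = {
        "mgf": outdir / "spectra.mgf",
        "scores": outdir / "scores.tsv",
        "absorbances": outdir / "absorbances.csv",
        "abundances": outdir / "abundances.csv",
    }
    write_mgf(spectra, paths["mgf"])
    validated = {s.id for s in lib_spectra}
    scores = generate_scores([s.id for s in spectra], validated, spec, rng)
    scores.to_csv(paths["scores"], sep="\t", index=False)
    # per-cultivar concentrations (uM) in the diluted measuring solution
    demo_conc = {name: conc for name, conc in zip(spec.cultivar_labels, (60.0, 59.0, 67.0))}
    frames = [
        generate_absorbances(conc, slope=0.004, intercept=0.0, noise_sd=0.002, n=4,
                             rng=rng, sample=name)
        for name, conc in demo_conc.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(paths["absorbances"], index=False)
    abundances = generate_abundances(library, spec, rng)
    abundances.to_csv(paths["abundances"], index_label="compound")
    return paths
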