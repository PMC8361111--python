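# flavoscreen

Fragment-based discovery, annotation, networking and quantification of
anthocyanins and related flavonoids in untargeted LC–MS/MS data, with a
focus on the acylated anthocyanins of purple-fleshed sweet potato.

## The problem

Purple sweet-potato roots accumulate anthocyanins — glycosylated, often
aromatically acylated anthocyanidin pigments of commercial interest as
natural colorants. In an untargeted LC–MS/MS experiment these compounds
hide among thousands of aligned peaks. Because anthocyanins ionize as
intact flavylium cations [M]+ and fragment predictably at their glycosidic
bonds, a spectrum that contains **both** an anthocyanidin aglycone fragment
and its mono- or disaccharide derivative is a strong flavonoid candidate.
`flavoscreen` implements that co-occurrence screen and the computational
stages around it as a tested, scriptable pipeline for anyone doing targeted
mining of pigment chemistry in plant metabolomics data.

## What it computes

* **Co-occurrence screen** — for aglycone nominal baits
  m/z ∈ {271, 287, 301, 303, 315, 317, 331, 345} (pelargonidin, cyanidin,
  peonidin, delphinidin, rosinidin, petunidin, malvidin, capensinidin) and
  sugar residues Δ ∈ {162, 146, 132} plus their six pairwise disaccharide
  sums, a singly charged spectrum hits when fragments near *A* and *A + Δ*
  both have intensity ≥ 3000 counts.
* **Mass arithmetic** — a composition (core + glycosyl residues + acyl
  residues) has cation m/z
  `m(core) + Σ m(sugar) + Σ m(acyl)`; the inverse (`decompose`) finds all
  compositions explaining an observed precursor within tolerance, resolving
  isobars such as caffeoyl (162.0317) vs hexose (162.0528) by accurate mass.
* **Library annotation** — matching against a bundled 18-entry library of
  sweet-potato anthocyanins (precursor + aglycone fragment + qualifying
  fragment evidence), with acylation classes Non/Mono/Di and
  aglycone calls including explicit ambiguity.
* **Mass-defect filter** — precursors with after-decimal m/z in
  [0.40, 0.80] are atypical of flavonoids and are removed unless rescued by
  in-house fragment evidence.
* **Classifier-score calibration** — the acceptance threshold for an
  external structural classifier's posterior scores is the minimum score of
  the validated anthocyanins; the candidate set is the union of the
  fragment screen and the score filter.
* **Molecular networking** — square-root-intensity-weighted cosine with
  greedy one-to-one peak matching (0.01 Da), edges at ≥ 0.70 similarity,
  node/edge TSV export.
* **pH-differential quantification** —
  `A = (A520 − A700)_pH1.0 − (A520 − A700)_pH4.5`, a cyanin standard curve
  (OLS), dilution correction `c1·V1 = c2·V2`, and mg cyanin-equivalents per
  g tissue.
* **Summaries** — percent composition, aglycone/acylation area ratios,
  Euclidean hierarchical clustering of cultivar profiles, and
  presence/absence set counts.

A seeded synthetic-data module generates every input the pipeline needs
(library-derived spectra, co-occurrence-violating decoys, mass-defect
contaminants, score tables, absorbance readings, abundance matrices).

## Worked example

```python
import flavoscreen as fs

blocks = fs.default_blocks()
c = fs.Composition(core=blocks["cyanidin"],
                   glycosyls=(blocks["hexose"],) * 3,
                   acyls=(blocks["caffeoyl"], blocks["p-hydroxybenzoyl"]))
print(round(fs.cation_mz(c), 2))                       # 1055.27
print([round(x, 2) for x in fs.expected_fragments(c)]) # [287.06, 449.11, 893.21]

s = fs.Spectrum(id="peak10.1", precursor_mz=1055.27, rt=3.52,
                fragments=(fs.FragmentPeak(287.06, 31000),
                           fs.FragmentPeak(449.11, 12000),
                           fs.FragmentPeak(893.21, 8000)))
(hit,) = fs.cooccurrence_screen([s])
print(hit.aglycone_nominal, hit.derivative_delta)      # 287 162

rec = fs.match(s, fs.load_library())
print(rec.entry.ygm_alias, rec.entry.acylation_class)  # YGM 1A Di
```

The composed cation mass 1055.27 is the diacylated cyanidin
(caffeoyl + p-hydroxybenzoyl sophoroside-glucoside); its evidence ions are
the bare cyanidin cation (287.06), cyanidin + one hexose (449.11) and the
precursor minus one hexose residue (893.21). The screen fires on the
287/449 pair (aglycone 287, Δ = 162) and annotation recovers the library
entry with zero precursor error.

Quantification from spectrophotometer readings:

```python
curve = fs.fit_standard_curve([(160 / 2**i, 0.004 * 160 / 2**i) for i in range(8)])
r = fs.AbsorbanceSet(a520_ph1=0.35, a700_ph1=0.02, a520_ph45=0.10, a700_ph45=0.01)
q = fs.quantify_sample(r, curve, extract_volume_l=0.05, tissue_mass_g=20.0)
print(round(q.differential_absorbance, 3),  # 0.24
      round(q.concentration_uM, 1),         # 60.0 (uM, cyanin equivalents)
      round(q.yield_dw, 4))                 # 0.0917 (mg/g dry weight)
```

A command-line interface mirrors the stages
(`flavoscreen simulate | screen | annotate | network | run-all ...`); see
`flavoscreen --help`.

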