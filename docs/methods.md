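# Methods

## Mass model

Anthocyanins are modelled as one anthocyanidin core plus multisets of
glycosyl and acyl residues. Cores carry flavylium **cation** masses
(neutral formula minus one electron, 0.00054858 Da — invisible at 2 dp but
fixed for consistency); sugars and acyl groups carry **residue** masses
(unit minus water), i.e. exactly what they add upon condensation.
Monoisotopic element masses: C 12, H 1.0078250319, O 15.9949146221.

| block | formula (as stored) | mass (Da) |
|---|---|---|
| cyanidin / peonidin cation | C15H11O6 / C16H13O6 | 287.0550 / 301.0707 |
| hexose / deoxyhexose / pentose residue | C6H10O5 / C6H10O4 / C5H8O4 | 162.0528 / 146.0579 / 132.0423 |
| caffeoyl / feruloyl / p-hydroxybenzoyl residue | C9H6O3 / C10H8O3 / C7H4O2 | 162.0317 / 176.0473 / 120.0211 |

Composition mass is strictly additive, so the inverse problem
(`decompose`) is a bounded exhaustive search: 8 cores × glycosyl multisets
up to size 4 × acyl multisets up to size 3 (one unit of headroom over the
largest library compound, which has 3 sugars and 2 acyls; bounds are
arguments). The default 0.01 Da tolerance cleanly separates the
caffeoyl/hexose isobar pair (21 mDa apart) at the masses in play.

**Observed vs theoretical masses.** The bundled library records *observed*
instrument m/z values. Although the instrument's average MS1 mass error is
~0.002 Da, individual printed values deviate from theory by up to
~0.011 Da (e.g. the 949.25/949.2608 pair shared by peonidin-caffeoyl and
cyanidin-feruloyl trisaccharides). Library load therefore validates
composition-vs-precursor consistency at 0.015 Da, and the mass-bookkeeping
tests assert agreement at 0.011 Da rather than exact 2-dp equality.

## Discovery screen

A spectrum passes when, for some aglycone nominal bait *A*, fragments
within ±0.5 Da of *A* and of *A + Δ* both have intensity ≥ 3000 counts,
with Δ a monosaccharide residue {162, 146, 132} or one of the six pairwise
disaccharide sums {324, 308, 294, 292, 278, 264}. Choices worth noting:

* **Floor boundary.** The fragment-intensity rule is stated both as
  "> 3000" and as "below 3000 removed" in common practice; the removal
  formulation is taken as authoritative, so intensity **≥ floor** is kept.
  The floor is configurable.
* **Nominal tolerance 0.5 Da** reproduces integer-nominal matching against
  accurate fragment masses; an accurate-mass mode (±0.01 Da against the
  accurate core masses) is available via the config.
* Both evidence fragments must support the **same** aglycone *A*; the
  intensity rule applies per fragment. One hit per (spectrum, aglycone),
  keeping the most intense derivative evidence.
* Doubly charged spectra are excluded by default (flavylium cations are
  singly charged); missing MGF CHARGE lines default to 1+ with a logged
  count.

**Mass-defect filter.** Precursors with after-decimal m/z in the closed
window [0.40, 0.80] (atypical of flavonoid elemental compositions) are
removed unless rescued by in-house evidence — in the pipeline, a
co-occurrence hit. The fractional part is rounded to 6 dp before the
comparison so printed boundary masses behave as written. Endpoints are
closed because the source description ("between") does not exclude them.

**Score calibration.** For an external classifier's posterior score table,
the threshold is the minimum score of the validated compounds for the
target class, and the filter keeps scores **≥** threshold. The strict ">"
formulation sometimes quoted would exclude the calibrating compound
itself; the inclusive boundary makes calibration self-consistent. The
candidate set entering networking is the union of screen hits and score
survivors.

## Annotation

Matching requires precursor agreement within 0.01 Da (5× headroom over the
instrument's average error), presence of an aglycone signature fragment
and of at least one qualifying fragment (all of them in `strict` mode).
Ranking: matched-fragment count, then absolute precursor error, then RT
error, then library order. The RT gate is **off by default** because
retention times shift across chromatographic setups; enabling it gates on
the library's recorded RTs and is what distinguishes co-eluting isomeric
entries (the same compound appears at three RTs in the library; without RT
they are indistinguishable by masses, which is correct behaviour at
compound level). One library peak has two defensible isobaric structures;
it is stored as a single entry whose ambiguous-core marker lists both
candidates, and aglycone classification reports ambiguity as a first-class
outcome whenever more than one core's accurate mass appears among
above-floor fragments.

Acylation class is the acyl-residue count: Non (0), Mono (1), Di (2),
Poly (>2). Of the 18 bundled entries, 2 are Non and 16 acylated.

## Molecular networking

The similarity metric of the original networking tool is not formally
specified, so the standard molecular-networking kernel is used: cosine of
intensity^0.5-weighted peak vectors under greedy highest-product
one-to-one peak pairing within 0.01 Da. Divergence from any particular
external tool's kernel is expected; exponent, tolerance and a
precursor-shift-aware (modified cosine) variant are configurable, the
latter off by default. Edges require similarity ≥ 0.70; spectra with no
edge are reported as isolated rather than silently dropped. For
well-separated peaks (spacing ≫ tolerance) the greedy pairing equals the
exhaustive optimal assignment, which is how the tests oracle it; an
independent implementation (matchms `CosineGreedy`) is used as a
cross-check in the test suite only.

## Quantification

`A = (A520 − A700)_pH1.0 − (A520 − A700)_pH4.5`, exactly; negative values
are logged and passed through. The standard curve is OLS **with**
intercept (the source protocol says only "linear regression"); a two-point
curve interpolates exactly. Concentration is inverse regression
`(A − b)/m` in µM; yield is
`conc · V_extract · M_standard / m_tissue` in mg/g. The cyanin standard's
molar mass defaults to the flavylium-cation basis (611.16 g/mol, computed
from cyanidin + 2 hexose residues); the chloride-salt basis (~35.5 g/mol
heavier) is selectable because protocols differ on which the mg/g values
use. Dilution correction is the identity `c2 = c1·V1/V2`. Fresh-weight
yield scales dry-weight yield by the dry-matter fraction
`(1 − water_content)`, with water content supplied per sample.

The serial-dilution generator defaults to **8** two-fold steps
(160 → 1.25 µM): a "7 concentrations from 160 to 1.25 µM" description is
internally inconsistent (that range spans 8 two-fold values), and the full
range is kept.

## Summaries

Percent composition divides each abundance by its cultivar total (×100);
a zero total is fatal for that cultivar. Group ratios are area fractions
by aglycone or acylation class, with ambiguous-core compounds as their own
category. Clustering is agglomerative with Euclidean metric and
**complete** linkage (a common heatmap default; single/average/ward are
accepted), with deterministic leaf order and a Newick rendering for
text-level inspection. Display matrices use log10(x + 1) to handle zeros;
statistics run on raw values. Presence/absence uses abundance > floor with
floor 0 by default.

## Synthetic data: what it emulates, and what it does not

The generator produces, from one integer seed (byte-identical outputs):

* **Library spectra** — one per library entry: the printed precursor, RT
  and evidence ions, intensities log-normal with median 10× the floor
  (σ = 0.5, clipped below at the floor so embedded evidence is never lost
  to sampling), plus sub-floor uniform noise fragments rejection-sampled
  at least 0.05 Da away from evidence ions.
* **Decoys** (default 50) — three cycled families: core fragment only,
  derivative fragment only, and both present but below the floor. Each
  carries at most one above-floor fragment, so no decoy can satisfy the
  two-fragment co-occurrence criterion at any floor at or above the
  configured one — a structural guarantee, not a statistical one.
* **Contaminants** — precursors with fractional m/z uniform in
  [0.40, 0.80]; above-floor fragments kept ≥ 0.6 Da from every bait
  target; alternating doubly charged spectra exercise the charge filter.
  The demo cohort sizes contaminants at `f/(1−f)` of the library + decoy
  count (f = 0.2 → 17); tests and the acceptance benchmark use an explicit
  20.
* **Score tables** — validated ids uniform in [minimum, 1] with one id
  pinned at the configured minimum 0.63337 so calibration recovers it;
  other ids uniform in [0, 1].
* **Absorbances** — replicate readings whose differential equals
  `slope·conc + intercept + N(0, σ)` over constant haze/baseline channels;
  defaults slope 0.004 AU/µM, σ 0.002 AU, 4 replicates.
* **Abundance matrices** — log-normal areas (median 1e6) per compound and
  cultivar with a configurable inclusion probability.

These synthetics deliberately omit chromatographic peak shapes, isotope
envelopes, adducts, in-source fragmentation and correlated instrument
noise. Passing the recovery tests therefore shows the *logic* of the
screen, filters and annotation is correct under the stated assumptions —
it does not certify recall or precision on real instrument data, where
co-eluting isobars and adducts are the dominant failure modes.

## Problem sizes and numerical choices

The bundled benchmark runs at desk scale: 18 library spectra + 50 decoys
+ 20 contaminants (88 spectra), all-pairs networking on tens of spectra,
and 200-composition inverse-search sweeps; the whole suite completes in
well under a minute. Dataset-level counts from full untargeted runs
(thousands of aligned peaks) depend on the deposited raw data and external
peak-picking/classification tools and are out of scope here.

Ties in annotation break deterministically (library order last); graph
exports sort rows; similarity values are rounded to 6 dp at the edge
level; cluster leaf order comes from the SciPy linkage encoding. Degenerate
inputs (empty spectra, empty graphs, single-leaf trees, zero-noise
generators) are all defined and tested rather than errors, except where a
computation is genuinely impossible (zero-slope curve, zero column total,
identical standard concentrations), which is fatal with a named cause.
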