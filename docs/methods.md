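# Methods

## Scope and data model

The pipeline operates downstream of formula assignment: inputs are a
peak table (neutral monoisotopic masses with element counts over
C/H/N/O/S/P, a ¹³C flag, and per-sample intensities), sample metadata,
and a transformation reference list. Raw-spectrum processing, peak
picking and formula assignment are out of scope. Masses are stored as
neutral monoisotopic masses; a config flag converts negative-mode m/z
by adding the proton mass (1.007276 Da). Peaks whose masses agree
within 1e-6 Da are merged with a union of detections — far tighter
than instrument alignment tolerances, so no genuinely distinct peaks
merge. All downstream statistics are presence/absence based;
intensities are carried through I/O but discarded by the analyses
(an intensity-weighted per-sample summary exists behind a flag).

## Filtering and molecular indices

Peaks are restricted to the high-confidence window 200–900 m/z
(inclusive endpoints; the filter is idempotent) and ¹³C isotopologues
are removed. For each assigned formula (charge fixed at 0):

- `DBE = 1 + C − H/2 + N/2 + P/2`
- `AI_mod = (1 + C − O/2 − S − H/2)/(C − O/2 − S − N − P)`, defined as
  0 when the denominator is ≤ 0 or the numerator negative — the usual
  convention in the aromaticity-index literature for degenerate
  compositions. `AI_mod > 0.5` marks aromatic, `≥ 0.67` condensed
  aromatic (so condensed implies aromatic).
- `NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C`, spanning −4 (CH₄) to +4
  (CO₂) for chemically meaningful formulas, and
  `ΔG°_Cox = 60.3 − 28.5·NOSC` in kJ (mol C)⁻¹.
- Kendrick defect with the floor convention, `km − ⌊km⌋ ∈ [0, 1)` with
  `km = mass·14/14.01565`; constant along CH₂ homologous series.

Elemental groups concatenate "CHO" with the heteroatoms present in the
canonical order N, S, P; formulas without C, H and O all present fall
into "other". Van Krevelen classes are rectangles in (O:C, H:C) space
read from a YAML config; the bundled default covers the eight classes
used for organic-matter panels, evaluated in declared precedence order
(first hit wins, which resolves overlaps deterministically; no hit is
"other"). The exact rectangle set is a documented choice, not a
derived quantity — users can substitute their preferred table.

Per-sample summaries (mean indices over detected assigned peaks,
count-fraction abundances of groups and classes, richness = number of
assigned peaks detected) use unweighted means by default. Samples with
zero assigned detections get richness 0 and missing means.

## Transformation inference

Pairwise mass differences within a sample (all retained peaks, no
formula needed) are matched against the reference list within a
tolerance of 1 ppm of the reference mass (an alternative basis, 1 ppm
of the heavier peak, is selectable). The matcher binary-searches
`m_i + ref` over the sorted mass list per reference — subquadratic in
practice — but applies the same closed-form acceptance inequality
`|(m_j − m_i) − ref| ≤ tol` as the exhaustive O(n²k) enumeration, so
its output is identical to the oracle's; the suite asserts exact set
equality over 100 random peak sets against the full list. Every
qualifying (pair, reference) match is reported: a pair may match
several references, including same-mass duplicates in the list.

Matched references are grouped as CHO-only, N-, S- and P-containing.
A reference with several heteroatoms counts in each category
(multi-membership; the exclusive N > S > P mode is behind a flag).
Category relative abundances are counts over total matches; they sum
to one exactly when every matched reference is single-category.

### The bundled reference list

`data/transformations_synthetic_1255.csv` is a synthetic stand-in
built deterministically by `riverchem.refbuild`: 57 named biochemical
moieties (amino-acid residues, sugar residues, small organic losses,
S- and P-moieties) plus their pairwise combinations in a fixed order,
truncated to exactly 1255 entries. Masses are monoisotopic sums from
the package's element masses, with one deliberate exception: phosphate
(HPO₃) carries the conventional reported value 79.9662 Da rather than
the recomputed 79.96633 Da, and combination masses inherit it. The
anchors used in worked examples are alanine 71.0371 (C₃H₅NO) and
phosphate 79.9662.

## Comparative statistics

PCA runs on the samples × peaks presence/absence matrix with columns
mean-centred and not variance-scaled (scaling is flag-switchable).
PERMANOVA uses the McArdle–Anderson partition on squared Euclidean
distances: `F = (SS_T − SS_W)/(a−1) / (SS_W/(n−a))` with
`p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`; permutations default to
999 and are fully vectorized. Samples are put in a canonical order
(group label, then squared-distance row sum) before permuting, so a
seeded p-value is invariant to input row order. Permuted statistics
that tie the observed one count toward the p-value — the standard
conservative convention — so with tiny groups the minimal p can exceed
1/(n_perm+1) when a random permutation recreates the observed
partition. Beta-dispersion computes each sample's distance to its
group centroid from the distance matrix alone via
`d²(i, c_g) = (1/n_g)Σ_{j∈g} d²_ij − (1/n_g²)Σ_{j<k∈g} d²_jk`
(exact for Euclidean distances; the spatial-median variant is not
implemented), and compares groups with a two-sided Mann–Whitney U
test. Univariate metric families are tested with two-sided
Mann–Whitney U (exact where ties permit, normal approximation
otherwise; fully tied data give p = 1) and Benjamini–Hochberg
adjustment within the family passed in one call — families are
defined per output table (indices; elemental groups; classes; the
four transformation categories).

## Chemogeography

Replicates are union-merged per site × environment: a metabolite
detected in any replicate is present at the site, so site presence
sets grow monotonically in replicates. Site profiles (mean indices,
abundances, richness over the union set) are restricted to a
contiguous-US bounding box and split at the St. Louis meridian
(−90.1994°): East strictly greater, sites exactly on the threshold go
West (fixed, documented tie rule). Per environment, East and West site
profiles are compared per metric family as above; each side must hold
at least two sites.

## Synthetic study generator

The generator emulates the study design so every stage is testable
offline: `n` sites per region (default 6 East + 6 West), surface water
and sediment at every site, triplicate samples (the field protocol's
replication), one shared formula pool.

**Formula pool.** For each Van Krevelen class, 150 formulas by default
are rejection-sampled: (O:C, H:C) uniform inside the class rectangle,
carbon 10–35, integer counts, heteroatoms at fixed background rates
(N: 0/1/2 at 0.55/0.35/0.10; S at 0.12; P at 0.08), hydrogen parity
adjusted so DBE is a non-negative integer, kept only if the formula
classifies back into the requested class with mass in 200–900 Da.
Pool masses are unique at 1e-5 Da. Peak masses then receive a small
Gaussian calibration error (default sd 0.001 Da), emulating residual
mass error after calibration; see "Design choices" for why this
default is non-zero. Auxiliary peaks exercise the filters: ¹³C
isotopologues (3% of the pool, at +1.00335 Da), unassigned random
masses (5%), and a few peaks outside the m/z window.

**Site structure.** Each site × environment draws a presence set from
the pool without replacement, weighted by per-environment class
weights; site richness is Normal (surface water 260 ± 20, sediment
200 ± 20, truncated), making surface water richer. Surface-water
weights favour lignin-, tannin- and condensed-hydrocarbon-like
classes; sediment favours lipid- and protein-like — which realizes the
surface-water excess of AI_mod, DBE and NOSC. East sediment
additionally tilts its draw weights by `exp(λ·(NOSC − class mean))`
(λ = 2.0): centring within class shifts oxidation state without
reshaping class composition, planting the East > West sediment NOSC
contrast while leaving class-abundance contrasts clean.

**Transformation planting.** Per site × environment and category, a
planting rate (fraction of site richness; surface water N-heavy at
0.16, sediment S/P-heavy at 0.11 each) selects source peaks and adds
partner peaks at exactly `source + reference mass`, using references
that belong to a single category. Rates are multiplied by a mean-one
lognormal per site × category (sd 0.4), modelling between-site
variation in transformation activity. Replicate detection is
Bernoulli i.i.d. (p = 0.9) given site presence — the simplest model
consistent with replicate-union merging — so a planted partner evades
all three replicates with probability 1e-3; the recoverability
guarantee is conditional on both endpoints being detected. Ground
truth records every pool peak and planted edge.

**What the generator does not emulate.** Instrument physics
(resolution, S/N, ionization bias), intensity structure beyond
presence, correlated replicate detection, true reaction networks
(planted edges are independent pairs, not pathways), and the
compositional richness of real organic matter (~10³ pool formulas vs.
~10⁴–10⁵ observed). Passing tests therefore demonstrate that the
statistics recover structure of the planted kind at desk scale, not
that real rivers exhibit it.

## Design choices and calibration

- **Exchangeable units.** Calibration and recovery checks run on
  replicate-union site profiles: under the generator, site ×
  environment presence sets are independent draws, so sites are
  exchangeable and permutation/rank null distributions are exact.
  Sample-level tests (which the pipeline also outputs) share
  within-site presence sets and are not exchangeable units; their
  p-values should be read descriptively.
- **Default mass jitter.** With exact formula-grid masses, incidental
  pairwise differences (CH₂, H₂O, CO₂ series within homologous
  classes) dominate the match sets and inherit the planted class
  composition, making the CHO-only category share systematically
  differ between environments — the opposite of the condition the
  generator is meant to emulate (CHO-only transformations
  indistinguishable between environments). The default 1 mDa jitter
  suppresses these grid coincidences; planted partners sit at exact
  offsets from the observed source mass and remain matched. Zero
  jitter is available (`mass_noise_sd=0`) and used where grid
  exactness itself is under test.
- **Planting-rate balance.** Reference-list entries duplicate masses
  within categories at different multiplicities (a planted CHO edge
  matches ~2.4 same-mass references, an N edge ~1.9, S ~1.3, P ~1.1),
  so raw planted counts inflate unevenly. The default CHO rates
  (surface water 0.06 of a 0.30 total, sediment 0.05 of 0.31) were
  chosen so the multiplicity-weighted CHO-only share is balanced
  across environments.
- **Null calibration scale.** The zeroed-contrast configuration is
  small (3 sites per region, 25 formulas per class, richness 120,
  199 permutations) so that a 1000-replicate sweep runs in under a
  minute; at this size the PERMANOVA rejection rate is exactly nominal
  up to Monte-Carlo ties and the exact 6-vs-6 Mann–Whitney test has
  size 0.0498 at nominal 0.05.
- **Recovery scale.** Planted-recovery sweeps run the full default
  configuration over 100 seeds (~100 s): each seed generates a study,
  merges replicates, and tests the class family, the
  transformation-category family, and the East/West index family per
  environment. Planted contrasts are required significant
  (FDR-adjusted p < 0.05) with the correct direction; the CHO-only
  environment contrast and the surface-water East/West NOSC contrast
  serve as unplanted controls.
- **Determinism.** All randomness flows from a single
  `numpy.random.Generator` seeded from the config; generation and the
  pipeline are byte-reproducible. Output tables carry a header comment
  with the config hash (over the analytic configuration, excluding the
  output path) and seed; the JSON manifest records configuration,
  versions and outputs.

## Known limitations

- Tolerance semantics follow "ppm of the reference mass" by default;
  for small reference masses this is a very narrow absolute window
  (1 ppm of H₂ is 2e-6 Da), which real mass accuracy would rarely
  satisfy — the per-pair basis is available where that matters.
- The Van Krevelen boundary table is a convention; class abundances
  are only comparable across studies using the same table.
- Beta-dispersion assumes Euclidean distances (centroids in coordinate
  space); non-Euclidean dissimilarities are out of scope.
- The East/West split uses a single meridian, not the river's course;
  sites between the meridian and the river are classified by longitude
  alone.
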