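# riverchem

Analysis pipeline for river-corridor environmental metabolomics by
ultrahigh-resolution mass spectrometry (FTICR-MS). Given a
formula-annotated peak table (one row per peak: calibrated neutral
mass, C/H/N/O/S/P counts, a ¹³C-isotopologue flag, one intensity column
per sample) and sample metadata (site, environment, replicate,
coordinates), the package computes per-formula molecular indices and
chemical classes, infers putative biochemical transformations from
pairwise mass differences, and runs the presence/absence chemodiversity
statistics used to compare surface-water and sediment metabolomes and
their spatial structure across the contiguous United States. A
synthetic-study generator reproduces the sampling design (sites ×
environments × triplicates, with plantable contrasts), so the entire
pipeline is exercisable and testable without any field data.

Intended users: biogeochemists and environmental-metabolomics groups
working with Formularity-style FTICR-MS exports who want a tested,
scriptable re-implementation of this analysis chain.

## The quantities at the core

For a neutral assigned formula C_c H_h N_n O_o S_s P_p (charge Z = 0):

- double-bond equivalents: `DBE = 1 + C − H/2 + N/2 + P/2`
- modified aromaticity index:
  `AI_mod = (1 + C − O/2 − S − H/2) / (C − O/2 − S − N − P)`,
  set to 0 when the denominator ≤ 0 or the numerator < 0;
  `AI_mod > 0.5` flags aromatic and `AI_mod ≥ 0.67` condensed-aromatic
  structures
- nominal oxidation state of carbon:
  `NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C`, and the standard Gibbs
  free energy of carbon oxidation `ΔG°_Cox = 60.3 − 28.5·NOSC`
  (kJ (mol C)⁻¹)
- Kendrick mass defect on the CH₂ repeat unit:
  `KMD = frac(mass · 14 / 14.01565)`
- elemental group (CHO, CHON, …, CHONSP) from the heteroatoms present,
  and Van Krevelen chemical class (lipid-like, protein-like, …,
  condensed-hydrocarbon-like) from the O:C and H:C ratios against a
  configurable rectangle table.

Transformation inference: for every pair of peaks detected in a sample
(formula assignment not required), the mass difference `m_j − m_i` is
matched against a bundled list of 1255 reference transformation masses
within 1 ppm (of the reference mass by default). A difference of
71.0371 Da, for example, is read as the gain or loss of an alanine
moiety, and 79.9662 Da as a phosphate. Matches are grouped into
CHO-only, N-, S- and P-containing categories and compared between
groups with two-sided Mann–Whitney U tests under Benjamini–Hochberg
FDR adjustment. Multivariate structure is assessed on presence/absence
matrices with column-centred (unscaled) PCA, Euclidean PERMANOVA
(McArdle–Anderson partition, permutation p-values), and beta-dispersion
(distance to group centroid). For spatial comparisons, replicates are
union-merged per site (a metabolite detected in any replicate counts
as present), and sites are split East/West at the longitude of the
Mississippi River at St. Louis (−90.1994°).

The bundled transformation list is a synthetic, deterministic stand-in
built from named biochemical moieties and their pairwise combinations
(`riverchem.refbuild`); it reproduces the anchor masses above exactly.

## Worked example

```
python analysis/01_simulate_study.py
python analysis/02_global_comparison.py
python analysis/03_transformations.py
python analysis/04_conus_east_west.py
```

The first script writes a synthetic study (12 sites × 2 environments ×
3 replicates = 72 samples, 2640 peaks, 1342 planted transformation
edges). The second prints, among others:

```
per-sample index comparison (surface water vs sediment):
  richness     adj p = 8.49e-11  direction: surface_water>sediment
  mean_ai_mod  adj p = 1.39e-06  direction: surface_water>sediment
  mean_dbe     adj p = 4.35e-09  direction: surface_water>sediment
  mean_nosc    adj p = 5.38e-11  direction: surface_water>sediment
PERMANOVA: pseudo-F = 4.0, R^2 = 0.055, p = 0.001 (999 permutations)
beta-dispersion means: {'sediment': 11.633, 'surface_water': 12.665}, Mann-Whitney p = 9.08e-11
```

i.e. the surface-water metabolome is richer, more aromatic, more
unsaturated, more oxidized and more dispersed in multivariate space
than sediment — exactly the contrasts the generator plants. The
transformation script shows surface water enriched in N-containing and
sediment in S-/P-containing transformation categories with CHO-only
quiet (adj p = 0.15), and the chemogeography script finds the planted
East > West sediment NOSC contrast (adj p = 0.0036) with no spatial
structure in surface water (adj p = 0.16).

The same pipeline runs from the shell on any dataset in the supported
CSV dialects:

```
riverchem simulate --seed 7 --out-dir mystudy
riverchem run-all --config config.yaml
```

where `config.yaml` names the peak table, metadata, output directory
and seed (see `riverchem.pipeline.PipelineConfig`).

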