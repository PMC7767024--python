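"""Desk-scale validation harness: null calibration and planted-effect recovery.

Two study-level checks that the statistics and the generator together
behave as designed:

* :func:`null_rejection` -- generate a study with every contrast zeroed
  and ask whether PERMANOVA (environment effect on site-level
  presence/absence) and the Mann-Whitney test (site mean NOSC) reject at
  a given alpha. Over many seeds the rejection rates should sit at the
  nominal level.

* :func:`planted_recovery` -- generate a study under the default
  (contrast-planting) configuration, run the site-level comparisons, and
  report adjusted p-values and directions for the planted contrasts
  (surface-water lignin/tannin excess, environment-specific N/S/P
  transformation planting, East-sediment NOSC excess) alongside
  deliberately unplanted ones (CHO-only transformations, surface-water
  East/West NOSC).

Both operate on replicate-union site profiles: under the generator's
detection model the site x environment presence sets are independent
draws, so sites are the exchangeable units and permutation/rank null
distributions are exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemistry import filter_peaks, peak_properties, summarize_samples
from .geography import east_west_compare, merge_replicates, site_summaries
from .io import load_bundled_transformations
from .simulate import GeneratorConfig, generate_study, null_config
from .stats import _mannwhitney, euclidean_distance, mannwhitney_fdr, permanova, presence_absence
from .transformations import compare_profiles, profile_mass_sets

_CLASS_FAMILY = [
    "class_lipid-like", "class_protein-like", "class_amino-sugar-like",
    "class_carbohydrate-like", "class_lignin-like", "class_tannin-like",
    "class_condensed-hydrocarbon-like", "class_unsaturated-hydrocarbon-like",
    "class_other",
]
_INDEX_FAMILY = ["richness", "mean_dbe", "mean_ai_mod", "mean_nosc", "mean_gfe"]


def site_level_summaries(study):
    """Filter, union-merge replicates, and compute site-level properties."""
    table = filter_peaks(study.table)
    site_table, site_meta = merge_replicates(table, study.metadata)
    props = peak_properties(site_table)
    return site_table, site_meta, props


def null_rejection(seed: int, n_permutations: int = 199, alpha: float = 0.05,
                   config: GeneratorConfig | None = None) -> dict:
    """One null-calibration replicate; returns the two rejection flags."""
    config = config if config is not None else null_config(seed)
    study = generate_study(config)
    site_table, site_meta, props = site_level_summaries(study)
    groups = site_meta["environment"]
    assigned = site_table.subset_peaks(props["has_formula"].to_numpy(bool))
    matrix = presence_absence(assigned)
    perm = permanova(euclidean_distance(matrix), groups,
                     n_permutations=n_permutations, seed=seed)
    summary = summarize_samples(site_table, props)
    nosc = summary["mean_nosc"]
    _, p_mw = _mannwhitney(
        nosc[(groups == "surface_water").to_numpy()].to_numpy(),
        nosc[(groups == "sediment").to_numpy()].to_numpy(),
    )
    return {
        "permanova_p": perm.p_value,
        "mannwhitney_p": p_mw,
        "permanova_reject": perm.p_value <= alpha,
        "mannwhitney_reject": p_mw <= alpha,
    }


def planted_recovery(seed: int, refs: pd.DataFrame | None = None,
                     tolerance_ppm: float = 1.0) -> dict:
    """One planted-effect recovery run at the default study conditions.

    Returns ``{check: (p_adjusted, direction)}`` for the planted and
    unplanted site-level contrasts.
    """
    if refs is None:
        refs = load_bundled_transformations()
    study = generate_study(GeneratorConfig(seed=seed), refs=refs)
    site_table, site_meta, props = site_level_summaries(study)
    groups = site_meta["environment"]
    summary = site_summaries(site_table, site_meta, props=props)

    classes = mannwhitney_fdr(summary[_CLASS_FAMILY], groups)
    classes = classes.set_index("metric")

    site_sets = {key: site_table.sample_masses(key) for key in site_table.sample_ids}
    profiles = profile_mass_sets(site_sets, refs, tolerance_ppm=tolerance_ppm)
    categories = compare_profiles(profiles, groups).set_index("metric")

    eastwest = east_west_compare(summary, families={"indices": _INDEX_FAMILY})
    ew_nosc = eastwest[eastwest["metric"] == "mean_nosc"].set_index("environment")

    out = {}
    for metric in ("class_lignin-like", "class_tannin-like"):
        row = classes.loc[metric]
        out[metric] = (float(row["p_adjusted"]), row["direction"])
    for cat in ("abund_N", "abund_S", "abund_P", "abund_CHO"):
        row = categories.loc[cat]
        out[cat] = (float(row["p_adjusted"]), row["direction"])
    for env in ("sediment", "surface_water"):
        row = ew_nosc.loc[env]
        out[f"eastwest_nosc_{env}"] = (float(row["p_adjusted"]), row["direction"])
    return out


PLANTED_EXPECTATIONS = {
    "class_lignin-like": "surface_water>sediment",
    "class_tannin-like": "surface_water>sediment",
    "abund_N": "surface_water>sediment",
    "abund_S": "sediment>surface_water",
    "abund_P": "sediment>surface_water",
    "eastwest_nosc_sediment": "East>West",
}

UNPLANTED_CHECKS = ("abund_CHO", "eastwest_nosc_surface_water")


def recovery_rates(seeds, alpha: float = 0.05, refs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Planted-detection and unplanted-false-positive rates over seeds."""
    if refs is None:
        refs = load_bundled_transformations()
    tallies = {name: 0 for name in list(PLANTED_EXPECTATIONS) + list(UNPLANTED_CHECKS)}
    seeds = list(seeds)
    for seed in seeds:
        result = planted_recovery(seed, refs=refs)
        for name, expected_dir in PLANTED_EXPECTATIONS.items():
            p, direction = result[name]
            if p < alpha and direction == expected_dir:
                tallies[name] += 1
        for name in UNPLANTED_CHECKS:
            p, _ = result[name]
            if p < alpha:
                tallies[name] += 1
    rows = []
    for name, count in tallies.items():
        kind = "planted" if name in PLANTED_EXPECTATIONS else "unplanted"
        rows.append({"check": name, "kind": kind, "rate": count / len(seeds)})
    return pd.DataFrame(rows)
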