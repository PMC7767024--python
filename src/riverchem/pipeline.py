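"""End-to-end analysis pipeline with config, manifest and CSV outputs.

The pipeline reproduces the study's two analysis tracks on any input
dataset (field export or synthetic fixture):

* the **global comparison** (surface water vs. sediment): pooled
  per-formula index distributions, per-sample elemental-group and
  chemical-class abundances, presence/absence PCA + Euclidean PERMANOVA
  + beta-dispersion, and transformation-category profiles;
* the **CONUS comparison** (East vs. West of the St. Louis meridian):
  replicate-union site profiles and per-environment Mann-Whitney/FDR
  comparisons of indices, groups and classes.

Every output table is CSV with a header comment carrying the config
hash and seed; a JSON manifest records the configuration, hash, seed
and library versions. Identical config + seed reproduce every output
byte for byte. Inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemistry import (
    INDEX_COLUMNS,
    VKBoundarySet,
    default_boundaries,
    filter_peaks,
    peak_properties,
    summarize_samples,
)
from .errors import ConfigError, ValidationError
from .geography import (
    CONUS_BOX,
    EAST_WEST_THRESHOLD,
    METRIC_FAMILIES,
    conus_filter,
    east_west_compare,
    merge_replicates,
    site_summaries,
    split_east_west,
)
from .io import (
    load_bundled_transformations,
    read_metadata,
    read_peak_table,
    read_transformation_list,
)
from .stats import beta_dispersion, euclidean_distance, mannwhitney_fdr, pca, permanova, presence_absence
from .transformations import compare_profiles, profile_mass_sets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``PipelineConfig.from_yaml``)."""

    peak_table: Path
    metadata: Path
    output_dir: Path
    seed: int
    transformations: Path | None = None
    boundaries: Path | None = None
    dialect: str = "formularity"
    mass_mode: str = "neutral"
    mz_min: float = 200.0
    mz_max: float = 900.0
    tolerance_ppm: float = 1.0
    tolerance_basis: str = "ref"
    n_permutations: int = 999
    east_west_threshold: float = EAST_WEST_THRESHOLD
    conus_box: dict = field(default_factory=lambda: dict(CONUS_BOX))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("config must provide a seed")
        self.peak_table = Path(self.peak_table)
        self.metadata = Path(self.metadata)
        self.output_dir = Path(self.output_dir)
        for name in ("peak_table", "metadata", "transformations", "boundaries"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"peak_table", "metadata", "output_dir", "seed"} - set(raw)
        if missing:
            raise ConfigError(f"config missing required keys: {sorted(missing)}")
        base = path.parent
        for key in ("peak_table", "metadata", "transformations", "boundaries", "output_dir"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else base / p
        return cls(**raw)

    def canonical_dict(self) -> dict:
        out = {}
        for name in sorted(self.__dataclass_fields__):
            value = getattr(self, name)
            out[name] = str(value) if isinstance(value, Path) else value
        return out

    @property
    def config_hash(self) -> str:
        """Hash of the analytic configuration (excludes the output path)."""
        payload = self.canonical_dict()
        payload.pop("output_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class Pipeline:
    """Loads inputs once and runs the analysis stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        cfg = config
        self.table = read_peak_table(cfg.peak_table, dialect=cfg.dialect, mass_mode=cfg.mass_mode)
        self.metadata = read_metadata(cfg.metadata)
        known = set(self.metadata["sample_id"])
        for sample in self.table.sample_ids:
            if sample not in known:
                raise ValidationError(f"sample without metadata: {sample!r}")
        if cfg.transformations is not None:
            self.refs = read_transformation_list(cfg.transformations)
        else:
            self.refs = load_bundled_transformations()
        self.boundaries: VKBoundarySet = (
            VKBoundarySet.from_yaml(cfg.boundaries) if cfg.boundaries else default_boundaries())
        self.filtered = filter_peaks(self.table, cfg.mz_min, cfg.mz_max)
        self.props = peak_properties(self.filtered, self.boundaries)
        self._env = self.metadata.set_index("sample_id")["environment"]
        self.outputs: list[str] = []

    # -- output helpers --------------------------------------------------

    def _header(self) -> str:
        return f"# config_hash={self.config.config_hash} seed={self.config.seed}\n"

    def _write(self, frame: pd.DataFrame, name: str, index: bool = False) -> Path:
        out_dir = self.config.output_dir
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / name
        with open(path, "w", newline="") as fh:
            fh.write(self._header())
            frame.to_csv(fh, index=index)
        self.outputs.append(name)
        return path

    def write_manifest(self) -> Path:
        manifest = {
            "config": self.config.canonical_dict(),
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "versions": {
                "riverchem": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_peaks_input": self.table.n_peaks,
            "n_peaks_filtered": self.filtered.n_peaks,
            "n_samples": len(self.table.sample_ids),
            "outputs": sorted(self.outputs),
        }
        path = self.config.output_dir / "run_manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    # -- stages -----------------------------------------------------------

    def sample_summaries(self) -> pd.DataFrame:
        summary = summarize_samples(self.filtered, self.props)
        merged = self.metadata.set_index("sample_id").join(summary)
        self._write(merged, "sample_summaries.csv", index=True)
        return merged

    def pooled_index_comparison(self) -> pd.DataFrame:
        """Pooled per-formula index distributions, one value per formula
        present in any sample of an environment (the figure-1 analogue)."""
        env_labels = sorted(self._env.unique())
        assigned = self.props["has_formula"].to_numpy(bool)
        presence = self.filtered.presence
        frames = []
        for env in env_labels:
            cols = [i for i, s in enumerate(self.filtered.sample_ids) if self._env[s] == env]
            in_env = presence[:, cols].any(axis=1) & assigned
            block = self.props.loc[in_env, list(INDEX_COLUMNS)].copy()
            block["environment"] = env
            frames.append(block)
        pooled = pd.concat(frames, ignore_index=True)
        comp = mannwhitney_fdr(pooled[list(INDEX_COLUMNS)], pooled["environment"])
        self._write(comp, "global_pooled_indices.csv")
        return comp

    def groupwise_abundance_comparison(self, summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
        out = {}
        for family, name in (("elemental_groups", "global_elemental_groups.csv"),
                             ("vk_classes", "global_vk_classes.csv"),
                             ("indices", "global_sample_indices.csv")):
            columns = [c for c in METRIC_FAMILIES[family] if c in summaries.columns]
            comp = mannwhitney_fdr(summaries[columns], summaries["environment"])
            comp.insert(0, "family", family)
            self._write(comp, name)
            out[family] = comp
        return out

    def ordination_and_dispersion(self) -> dict:
        assigned = self.filtered.subset_peaks(self.props["has_formula"].to_numpy(bool))
        matrix = presence_absence(assigned)
        ordination = pca(matrix)
        scores = ordination.scores.copy()
        scores.insert(0, "environment", self._env.reindex(scores.index))
        self._write(scores, "global_pca_scores.csv", index=True)
        variance = pd.DataFrame({
            "component": ordination.scores.columns,
            "proportion_variance": ordination.proportion_variance,
        })
        self._write(variance, "global_pca_variance.csv")
        self._write(ordination.loadings.head(2000), "global_pca_loadings.csv", index=True)

        dist = euclidean_distance(matrix)
        groups = self._env.reindex(matrix.index)
        perm = permanova(dist, groups, n_permutations=self.config.n_permutations,
                         seed=self.config.seed)
        self._write(pd.DataFrame([{
            "pseudo_f": perm.pseudo_f, "r_squared": perm.r_squared,
            "p_value": perm.p_value, "n_permutations": perm.n_permutations,
        }]), "global_permanova.csv")
        disp = beta_dispersion(dist, groups)
        disp_frame = pd.DataFrame({
            "sample_id": disp.distances.index,
            "environment": groups.to_numpy(),
            "distance_to_centroid": disp.distances.to_numpy(),
        })
        self._write(disp_frame, "global_dispersion_distances.csv")
        self._write(pd.DataFrame([{
            "group_a": disp.group_means.index[0], "mean_a": disp.group_means.iloc[0],
            "group_b": disp.group_means.index[1], "mean_b": disp.group_means.iloc[1],
            "u_statistic": disp.u_statistic, "p_value": disp.p_value,
        }]), "global_dispersion_test.csv")
        return {"pca": ordination, "permanova": perm, "dispersion": disp}

    def transformation_comparison(self) -> dict[str, pd.DataFrame]:
        cfg = self.config
        mass_sets = {s: self.filtered.sample_masses(s) for s in self.filtered.sample_ids}
        profiles = profile_mass_sets(mass_sets, self.refs,
                                     tolerance_ppm=cfg.tolerance_ppm, basis=cfg.tolerance_basis)
        merged = profiles.join(self._env)
        self._write(merged, "transformation_profiles.csv", index=True)
        comp = compare_profiles(profiles, self._env)
        self._write(comp, "transformation_category_tests.csv")
        return {"profiles": merged, "tests": comp}

    def run_global(self) -> dict:
        summaries = self.sample_summaries()
        results = {
            "summaries": summaries,
            "pooled_indices": self.pooled_index_comparison(),
            "abundances": self.groupwise_abundance_comparison(summaries),
            "ordination": self.ordination_and_dispersion(),
            "transformations": self.transformation_comparison(),
        }
        self.write_manifest()
        return results

    def run_conus(self) -> dict:
        cfg = self.config
        site_table, site_meta = merge_replicates(self.filtered, self.metadata)
        site_props = peak_properties(site_table, self.boundaries)
        profiles = site_summaries(site_table, site_meta, props=site_props)
        labelled = split_east_west(conus_filter(profiles, cfg.conus_box), cfg.east_west_threshold)
        self._write(labelled, "site_summaries.csv", index=True)

        long_rows = labelled.reset_index().melt(
            id_vars=["site_key", "site_id", "environment", "latitude", "longitude",
                     "n_replicates", "region"],
            var_name="metric", value_name="value")
        self._write(long_rows, "site_metrics_long.csv")

        comparisons = east_west_compare(profiles, threshold=cfg.east_west_threshold, box=cfg.conus_box)
        self._write(comparisons, "eastwest_comparisons.csv")

        site_sets = {key: site_table.sample_masses(key) for key in site_table.sample_ids}
        site_profiles = profile_mass_sets(site_sets, self.refs,
                                          tolerance_ppm=cfg.tolerance_ppm, basis=cfg.tolerance_basis)
        env_of_site = site_meta["environment"]
        merged_profiles = site_profiles.join(env_of_site)
        self._write(merged_profiles, "site_transformation_profiles.csv", index=True)
        cat_tests = compare_profiles(site_profiles, env_of_site)
        self._write(cat_tests, "site_transformation_category_tests.csv")
        self.write_manifest()
        return {
            "site_profiles": labelled,
            "eastwest": comparisons,
            "site_transformations": merged_profiles,
            "site_category_tests": cat_tests,
        }

    def run_all(self) -> dict:
        results = self.run_global()
        results.update(self.run_conus())
        return results


def run_global_comparison(config: PipelineConfig) -> dict:
    """Run the surface-water vs. sediment comparison bundle."""
    return Pipeline(config).run_global()


def run_conus_comparison(config: PipelineConfig) -> dict:
    """Run the site-level East/West comparison bundle."""
    return Pipeline(config).run_conus()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage."""
    return Pipeline(config).run_all()
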