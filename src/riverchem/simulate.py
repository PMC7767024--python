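"""Synthetic study generator.

Emulates the sampling design of a continental river-corridor survey so
every pipeline stage is exercisable without field data: sites in two
regions (east and west of the dividing meridian), surface water and
sediment at every site, triplicate samples per site/environment, and a
shared pool of chemically valid CHNOSP formulas spanning the Van
Krevelen classes.

Planted structure (all magnitudes are configurable and can be zeroed):

* **environment contrast** -- surface water draws more lignin-, tannin-
  and condensed-hydrocarbon-like formulas and is richer, sediment more
  lipid- and protein-like, reproducing the surface-water excess of
  aromaticity, unsaturation and oxidation state;
* **transformation contrast** -- partner peaks are planted at exact
  reference-mass offsets, with more N-moiety partners in surface water
  and more S-/P-moiety partners in sediment;
* **spatial contrast** -- sediment sites in the East tilt their draws
  toward oxidized (high-NOSC) formulas; surface water has no planted
  spatial structure.

Replicate-level detection is Bernoulli i.i.d. given site presence, the
simplest model consistent with replicate-union merging. Peak masses
carry a small Gaussian calibration error by default (planted partner
peaks sit at exact reference offsets from the observed source mass, so
planted edges always match); set ``mass_noise_sd=0`` for exact
formula-grid masses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chemistry import VK_CLASSES, VKBoundarySet, default_boundaries
from .errors import ConfigError, ValidationError
from .formulas import MONOISOTOPIC, MolecularFormula
from .io import PeakTable, write_metadata, write_peak_table

logger = logging.getLogger(__name__)

#: 13C - 12C mass difference (Da), used for isotopologue peaks.
C13_OFFSET = 1.0033548378

ENV_SURFACE = "surface_water"
ENV_SEDIMENT = "sediment"

_DEFAULT_CLASS_WEIGHTS = {
    ENV_SURFACE: {
        "lipid-like": 0.09, "protein-like": 0.12, "amino-sugar-like": 0.07,
        "carbohydrate-like": 0.17, "lignin-like": 0.30, "tannin-like": 0.14,
        "condensed-hydrocarbon-like": 0.07, "unsaturated-hydrocarbon-like": 0.04,
    },
    ENV_SEDIMENT: {
        "lipid-like": 0.20, "protein-like": 0.23, "amino-sugar-like": 0.08,
        "carbohydrate-like": 0.11, "lignin-like": 0.21, "tannin-like": 0.07,
        "condensed-hydrocarbon-like": 0.03, "unsaturated-hydrocarbon-like": 0.07,
    },
}

_DEFAULT_TRANSFORMATION_RATES = {
    ENV_SURFACE: {"N": 0.16, "S": 0.04, "P": 0.04, "CHO": 0.06},
    ENV_SEDIMENT: {"N": 0.04, "S": 0.11, "P": 0.11, "CHO": 0.05},
}


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic generator.

    Defaults describe a desk-scale survey: 6 sites per region, both
    environments at every site, triplicate sampling, a pool of 150
    formulas per Van Krevelen class, surface water richer than sediment,
    and the three planted contrasts described in the module docstring.
    """

    seed: int
    n_sites_east: int = 6
    n_sites_west: int = 6
    n_replicates: int = 3
    n_pool_per_class: int = 150
    richness_mean: Mapping[str, float] = field(
        default_factory=lambda: {ENV_SURFACE: 260.0, ENV_SEDIMENT: 200.0})
    richness_sd: float = 20.0
    class_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {e: dict(w) for e, w in _DEFAULT_CLASS_WEIGHTS.items()})
    east_sediment_nosc_tilt: float = 2.0
    transformation_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {e: dict(r) for e, r in _DEFAULT_TRANSFORMATION_RATES.items()})
    detection_prob: float = 0.9
    rate_site_sd: float = 0.4
    mass_noise_sd: float = 0.001
    c13_fraction: float = 0.03
    unassigned_fraction: float = 0.05
    extra_site_prob: float = 0.5
    mz_min: float = 200.0
    mz_max: float = 900.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("generator seed is mandatory")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigError("detection_prob must be in [0, 1]")
        for frac in (self.c13_fraction, self.unassigned_fraction, self.extra_site_prob):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must be in [0, 1]")
        for env in (ENV_SURFACE, ENV_SEDIMENT):
            if self.richness_mean[env] <= 0:
                raise ConfigError("richness means must be positive")
            weights = self.class_weights[env]
            if set(weights) != set(VK_CLASSES):
                raise ConfigError(f"class weights for {env} must cover all classes")
            if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ConfigError("class weights must be non-negative and sum > 0")
            rates = self.transformation_rates[env]
            if any(r < 0 for r in rates.values()):
                raise ConfigError("transformation rates must be non-negative")


def null_config(seed: int, **overrides) -> GeneratorConfig:
    """A configuration with every planted contrast zeroed.

    Both environments share uniform class weights, equal richness and
    zero transformation planting; there is no spatial tilt. Sized small
    (3 sites per region, 25 formulas per class) for calibration sweeps.
    """
    uniform = {name: 1.0 / len(VK_CLASSES) for name in VK_CLASSES}
    zero = {"N": 0.0, "S": 0.0, "P": 0.0, "CHO": 0.0}
    defaults = dict(
        seed=seed,
        n_sites_east=3, n_sites_west=3,
        n_pool_per_class=25,
        richness_mean={ENV_SURFACE: 120.0, ENV_SEDIMENT: 120.0},
        richness_sd=10.0,
        class_weights={ENV_SURFACE: dict(uniform), ENV_SEDIMENT: dict(uniform)},
        east_sediment_nosc_tilt=0.0,
        transformation_rates={ENV_SURFACE: dict(zero), ENV_SEDIMENT: dict(zero)},
        c13_fraction=0.0,
        unassigned_fraction=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@dataclass
class GroundTruth:
    """Traceability record: the true peak pool and planted edges."""

    pool: pd.DataFrame          # every generated peak, with uid/kind/class
    edges: pd.DataFrame         # planted transformation edges
    site_sets: dict             # (site_id, environment) -> array of peak uids


@dataclass
class StudyData:
    table: PeakTable
    metadata: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_peak_table(self.table, out_dir / "peak_table.csv")
        write_metadata(self.metadata, out_dir / "metadata.csv")
        self.truth.edges.to_csv(out_dir / "ground_truth_edges.csv", index=False)
        self.truth.pool.to_csv(out_dir / "ground_truth_pool.csv", index=False)


# ---------------------------------------------------------------------------
# formula pool
# ---------------------------------------------------------------------------

_ELEMENT_MASS = np.array([MONOISOTOPIC[e] for e in ("C", "H", "N", "O", "S", "P")])


def _vector_mass(counts: np.ndarray) -> np.ndarray:
    return counts @ _ELEMENT_MASS


def build_formula_pool(
    config: GeneratorConfig,
    boundaries: VKBoundarySet | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Rejection-sample a pool of chemically valid CHNOSP formulas.

    For each Van Krevelen class, candidate (O:C, H:C) points are drawn
    inside the class rectangle, converted to integer element counts,
    given heteroatoms at fixed background probabilities, parity-adjusted
    so DBE is a non-negative integer, and kept only if they land back in
    the requested class with mass inside the instrument window. Pool
    masses are unique at 1e-5 Da.
    """
    if boundaries is None:
        boundaries = default_boundaries()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rect_by_name = {r.name: r for r in boundaries.rectangles}
    seen_masses: set[float] = set()
    frames = []
    for class_name in VK_CLASSES:
        rect = rect_by_name.get(class_name)
        if rect is None:
            raise ConfigError(f"boundary table lacks class {class_name!r}")
        oc_lo, oc_hi = rect.oc_min, rect.oc_max
        hc_lo, hc_hi = rect.hc_min, rect.hc_max
        if oc_hi <= oc_lo or hc_hi <= hc_lo:
            raise ConfigError(f"empty rectangle for class {class_name!r}")
        oc_pad = 0.02 * (oc_hi - oc_lo)
        hc_pad = 0.02 * (hc_hi - hc_lo)
        need = config.n_pool_per_class
        collected: list[np.ndarray] = []
        for _ in range(200):
            if need <= 0:
                break
            m = 4 * need + 40
            c = rng.integers(10, 36, m)
            oc = rng.uniform(oc_lo + oc_pad, oc_hi - oc_pad, m)
            hc = rng.uniform(hc_lo + hc_pad, hc_hi - hc_pad, m)
            o = np.clip(np.round(oc * c), 1, None).astype(int)
            h = np.clip(np.round(hc * c), 1, None).astype(int)
            n = rng.choice([0, 1, 2], size=m, p=[0.55, 0.35, 0.10])
            s = (rng.random(m) < 0.12).astype(int)
            p = (rng.random(m) < 0.08).astype(int)
            h = h + (h + n + p) % 2  # integer DBE for a neutral molecule
            counts = np.column_stack([c, h, n, o, s, p])
            dbe = 1.0 + c - h / 2.0 + n / 2.0 + p / 2.0
            mass = _vector_mass(counts)
            ok = (dbe >= 0) & (mass >= config.mz_min) & (mass <= config.mz_max)
            ok &= boundaries.classify(o / c, h / c) == class_name
            for row, row_mass in zip(counts[ok], mass[ok]):
                key = round(float(row_mass), 5)
                if key in seen_masses:
                    continue
                seen_masses.add(key)
                collected.append(row)
                need -= 1
                if need <= 0:
                    break
        if need > 0:
            raise ConfigError(
                f"could not sample {config.n_pool_per_class} formulas for class {class_name!r}")
        block = pd.DataFrame(np.array(collected), columns=["c", "h", "n", "o", "s", "p"])
        block["vk_class"] = class_name
        frames.append(block)
    pool = pd.concat(frames, ignore_index=True)
    counts = pool[["c", "h", "n", "o", "s", "p"]].to_numpy(float)
    pool.insert(0, "mass", _vector_mass(counts))
    c, h, n, o, s, p = counts.T
    pool["nosc"] = 4.0 - (4.0 * c + h - 3.0 * n - 2.0 * o + 5.0 * p - 2.0 * s) / c
    pool["is_c13"] = False
    pool["kind"] = "formula"
    return pool


# ---------------------------------------------------------------------------
# transformation planting
# ---------------------------------------------------------------------------

def _pure_category_mask(refs: pd.DataFrame, category: str) -> np.ndarray:
    has_n = refs["contains_n"].to_numpy(bool)
    has_s = refs["contains_s"].to_numpy(bool)
    has_p = refs["contains_p"].to_numpy(bool)
    if category == "N":
        return has_n & ~has_s & ~has_p
    if category == "S":
        return has_s & ~has_n & ~has_p
    if category == "P":
        return has_p & ~has_n & ~has_s
    if category == "CHO":
        return ~has_n & ~has_s & ~has_p
    raise ValidationError(f"unknown transformation category: {category!r}")


def plant_transformations(
    pool: pd.DataFrame,
    refs: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
    category: str | None = None,
    mz_max: float = 900.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant partner peaks at exact reference-mass offsets.

    ``round(rate * len(pool))`` source peaks are chosen (with
    replacement) and each gains a partner at ``source mass + reference
    mass``; partners falling above ``mz_max`` are skipped with a log
    message. When the reference composition is known and the source has
    a formula, the partner inherits the summed formula.

    Returns the augmented pool (original rows plus appended partners)
    and the planted-edge record.
    """
    if rate < 0:
        raise ValidationError("planting rate must be non-negative")
    if len(refs) == 0:
        raise ValidationError("reference list is empty")
    usable = refs if category is None else refs.loc[_pure_category_mask(refs, category)]
    usable = usable.reset_index(drop=True)
    if len(usable) == 0:
        raise ValidationError(f"no usable references for category {category!r}")
    n_edges = int(round(rate * len(pool)))
    edge_cols = ["source_mass", "partner_mass", "ref_name", "ref_mass", "category"]
    if n_edges == 0:
        return pool.copy(), pd.DataFrame(columns=edge_cols)
    src_idx = rng.integers(0, len(pool), n_edges)
    ref_idx = rng.integers(0, len(usable), n_edges)
    new_rows = []
    edges = []
    for si, ri in zip(src_idx, ref_idx):
        src = pool.iloc[si]
        ref = usable.iloc[ri]
        partner_mass = float(src["mass"]) + float(ref["mass"])
        if partner_mass > mz_max:
            logger.debug("skipping planted edge: partner mass %.4f above %.0f", partner_mass, mz_max)
            continue
        row = {"mass": partner_mass, "c": 0, "h": 0, "n": 0, "o": 0, "s": 0, "p": 0,
               "vk_class": "other", "nosc": np.nan, "is_c13": False, "kind": "partner"}
        comp = ref.get("composition")
        if isinstance(comp, str) and comp and comp.lower() != "nan" and src["c"] >= 1:
            combined = MolecularFormula(
                c=int(src["c"]), h=int(src["h"]), n=int(src["n"]),
                o=int(src["o"]), s=int(src["s"]), p=int(src["p"]),
            ) + MolecularFormula.from_string(comp)
            row.update(c=combined.c, h=combined.h, n=combined.n,
                       o=combined.o, s=combined.s, p=combined.p)
        new_rows.append(row)
        edges.append({
            "source_mass": float(src["mass"]), "partner_mass": partner_mass,
            "ref_name": ref["name"], "ref_mass": float(ref["mass"]),
            "category": category if category is not None else "any",
        })
    augmented = pd.concat([pool, pd.DataFrame(new_rows)], ignore_index=True) if new_rows else pool.copy()
    return augmented, pd.DataFrame(edges, columns=edge_cols)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(
    config: GeneratorConfig,
    refs: pd.DataFrame | None = None,
    boundaries: VKBoundarySet | None = None,
) -> StudyData:
    """Generate a complete synthetic study (peak table + metadata + truth).

    Deterministic given ``config.seed``: the same configuration always
    produces byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    if boundaries is None:
        boundaries = default_boundaries()
    if refs is None:
        from .io import load_bundled_transformations
        refs = load_bundled_transformations()

    pool = build_formula_pool(config, boundaries=boundaries, rng=rng)
    n_pool = len(pool)
    pool_class = pool["vk_class"].to_numpy(object)
    pool_nosc = pool["nosc"].to_numpy(float)

    # Auxiliary peaks: 13C isotopologues, unassigned masses, and a few
    # peaks outside the trusted m/z window (all removed or ignored by the
    # standard filtering / formula-dependent stages).
    aux_rows = []
    n_c13 = int(round(config.c13_fraction * n_pool))
    if n_c13:
        src = rng.choice(n_pool, n_c13, replace=False)
        for i in src:
            aux_rows.append({"mass": float(pool["mass"].iloc[i]) + C13_OFFSET,
                             "c": 0, "h": 0, "n": 0, "o": 0, "s": 0, "p": 0,
                             "vk_class": "other", "nosc": np.nan, "is_c13": True, "kind": "c13"})
    n_unassigned = int(round(config.unassigned_fraction * n_pool))
    for mass in rng.uniform(config.mz_min, config.mz_max, n_unassigned):
        aux_rows.append({"mass": float(mass), "c": 0, "h": 0, "n": 0, "o": 0, "s": 0, "p": 0,
                         "vk_class": "other", "nosc": np.nan, "is_c13": False, "kind": "unassigned"})
    if config.c13_fraction > 0 or config.unassigned_fraction > 0:
        for mass in np.concatenate([
            rng.uniform(max(50.0, config.mz_min - 80.0), config.mz_min - 1.0, 3),
            rng.uniform(config.mz_max + 1.0, config.mz_max + 80.0, 3),
        ]):
            aux_rows.append({"mass": float(mass), "c": 0, "h": 0, "n": 0, "o": 0, "s": 0, "p": 0,
                             "vk_class": "other", "nosc": np.nan, "is_c13": False, "kind": "out_of_range"})
    aux = pd.DataFrame(aux_rows) if aux_rows else pd.DataFrame()

    # Residual mass-calibration error, applied to pool and auxiliary
    # masses BEFORE transformation planting: planted partners sit at
    # exact reference offsets from the observed (noisy) source mass, so
    # planted edges stay recoverable while coincidental formula-grid
    # differences are perturbed off the matching window.
    if config.mass_noise_sd > 0:
        pool["mass"] = pool["mass"].to_numpy(float) + rng.normal(0.0, config.mass_noise_sd, n_pool)
        if len(aux):
            aux["mass"] = aux["mass"].to_numpy(float) + rng.normal(0.0, config.mass_noise_sd, len(aux))

    # Site metadata.
    sites = []
    for r in range(config.n_sites_east):
        sites.append({"site_id": f"E{r+1:02d}", "region": "East",
                      "latitude": float(rng.uniform(30.0, 47.0)),
                      "longitude": float(rng.uniform(-89.5, -75.0))})
    for r in range(config.n_sites_west):
        sites.append({"site_id": f"W{r+1:02d}", "region": "West",
                      "latitude": float(rng.uniform(30.0, 47.0)),
                      "longitude": float(rng.uniform(-124.0, -96.0))})

    class_weight_vectors = {}
    class_counts = pd.Series(pool_class).value_counts()
    for env in (ENV_SURFACE, ENV_SEDIMENT):
        w_class = config.class_weights[env]
        weights = np.array([w_class[c] / class_counts[c] for c in pool_class], float)
        class_weight_vectors[env] = weights / weights.sum()
    # Spatial tilt centred within each class: favours the more oxidized
    # members of every class without reshaping class composition.
    class_mean_nosc = pd.Series(pool_nosc).groupby(pd.Series(pool_class)).transform("mean").to_numpy()
    centred_nosc = pool_nosc - class_mean_nosc

    # Partner-peak registry so identical planted partners are one peak.
    partner_rows: list[dict] = []
    partner_uid_by_mass: dict[float, int] = {}
    edges_out = []
    site_sets: dict[tuple[str, str], np.ndarray] = {}
    n_aux = len(aux)
    # uid layout: pool [0, n_pool), aux [n_pool, n_pool+n_aux), partners after.
    for site in sites:
        for env in (ENV_SURFACE, ENV_SEDIMENT):
            richness = int(round(rng.normal(config.richness_mean[env], config.richness_sd)))
            richness = int(np.clip(richness, 20, n_pool))
            weights = class_weight_vectors[env]
            if env == ENV_SEDIMENT and site["region"] == "East" and config.east_sediment_nosc_tilt:
                tilted = weights * np.exp(config.east_sediment_nosc_tilt * centred_nosc)
                weights = tilted / tilted.sum()
            chosen = np.sort(rng.choice(n_pool, size=richness, replace=False, p=weights))
            uids = [int(u) for u in chosen]
            site_pool = pool.iloc[chosen].reset_index(drop=True)
            for category, rate in sorted(config.transformation_rates[env].items()):
                if rate <= 0:
                    continue
                if config.rate_site_sd > 0:
                    # Between-site variability in transformation activity:
                    # a mean-one lognormal multiplier per site x category.
                    rate = rate * rng.lognormal(-0.5 * config.rate_site_sd ** 2,
                                                config.rate_site_sd)
                _, edges = plant_transformations(
                    site_pool, refs, rate, rng, category=category, mz_max=config.mz_max)
                for edge in edges.itertuples(index=False):
                    key = edge.partner_mass
                    uid = partner_uid_by_mass.get(key)
                    if uid is None:
                        uid = n_pool + n_aux + len(partner_rows)
                        partner_uid_by_mass[key] = uid
                        partner_rows.append({
                            "mass": edge.partner_mass, "c": 0, "h": 0, "n": 0, "o": 0,
                            "s": 0, "p": 0, "vk_class": "other", "nosc": np.nan,
                            "is_c13": False, "kind": "partner"})
                    uids.append(uid)
                    edges_out.append({
                        "site_id": site["site_id"], "environment": env,
                        "source_mass": edge.source_mass, "partner_mass": edge.partner_mass,
                        "ref_name": edge.ref_name, "ref_mass": edge.ref_mass,
                        "category": category,
                    })
            if n_aux:
                extra = np.flatnonzero(rng.random(n_aux) < config.extra_site_prob)
                uids.extend(int(n_pool + e) for e in extra)
            site_sets[(site["site_id"], env)] = np.unique(np.array(uids, dtype=int))

    all_peaks = pd.concat([pool, aux, pd.DataFrame(partner_rows)], ignore_index=True) \
        if (n_aux or partner_rows) else pool.copy()
    all_peaks["uid"] = np.arange(len(all_peaks))

    # Replicate-level detection.
    meta_rows = []
    detections = {}
    n_total = len(all_peaks)
    env_short = {ENV_SURFACE: "SW", ENV_SEDIMENT: "SED"}
    for site in sites:
        for env in (ENV_SURFACE, ENV_SEDIMENT):
            present = np.zeros(n_total, bool)
            present[site_sets[(site["site_id"], env)]] = True
            for rep in range(config.n_replicates):
                sample_id = f"{site['site_id']}_{env_short[env]}_{rep+1}"
                detected = present & (rng.random(n_total) < config.detection_prob)
                intensity = np.zeros(n_total)
                intensity[detected] = np.round(rng.lognormal(14.0, 1.0, int(detected.sum())), 1)
                detections[sample_id] = intensity
                meta_rows.append({
                    "sample_id": sample_id, "site_id": site["site_id"],
                    "environment": env, "replicate": f"rep{rep+1}",
                    "latitude": site["latitude"], "longitude": site["longitude"],
                })

    peaks_frame = all_peaks[["mass", "c", "h", "n", "o", "s", "p", "is_c13"]]
    table = PeakTable.from_frames(peaks_frame, pd.DataFrame(detections))
    metadata = pd.DataFrame(meta_rows)
    edge_cols = ["site_id", "environment", "source_mass", "partner_mass",
                 "ref_name", "ref_mass", "category"]
    truth = GroundTruth(
        pool=all_peaks,
        edges=pd.DataFrame(edges_out, columns=edge_cols),
        site_sets=site_sets,
    )
    return StudyData(table=table, metadata=metadata, truth=truth)
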