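"""Per-formula molecular indices and chemical classification.

Given an assigned molecular formula C_c H_h N_n O_o S_s P_p of a neutral
molecule (charge Z = 0), the package computes:

* **DBE** (double-bond equivalents), the rings-plus-double-bonds count::

      DBE = 1 + C - H/2 + N/2 + P/2

* **AI_Mod** (modified aromaticity index)::

      AI_Mod = (1 + C - O/2 - S - H/2) / (C - O/2 - S - N - P)

  clamped to 0 when the denominator is <= 0 or the numerator is < 0.
  AI_Mod > 0.5 marks aromatic and AI_Mod >= 0.67 condensed-aromatic
  structures.

* **NOSC** (nominal oxidation state of carbon)::

      NOSC = 4 - (4C + H - 3N - 2O + 5P - 2S) / C

  and the associated standard Gibbs free energy of carbon oxidation
  (kJ per mol C)::

      GFE = 60.3 - 28.5 * NOSC

* the **Kendrick mass defect** on the CH2 repeat unit (fractional part of
  ``mass * 14 / 14.01565``), constant along a CH2 homologous series;

* the **elemental group** (CHO, CHON, ..., CHONSP) and the **Van
  Krevelen chemical class** from the O:C and H:C ratios against a
  configurable rectangle table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .formulas import MolecularFormula
from .io import PeakTable

logger = logging.getLogger(__name__)

#: CH2 repeat-unit mass (Da) used for the Kendrick rescaling.
CH2_MASS = 14.01565

#: AI_Mod thresholds for aromatic and condensed-aromatic character.
AROMATIC_THRESHOLD = 0.5
CONDENSED_AROMATIC_THRESHOLD = 0.67

#: Closed label set for heteroatom (elemental) groups, canonical order.
ELEMENTAL_GROUPS = ("CHO", "CHON", "CHOS", "CHOP", "CHONS", "CHONP", "CHOSP", "CHONSP")

VK_CLASSES = (
    "lipid-like",
    "protein-like",
    "amino-sugar-like",
    "carbohydrate-like",
    "lignin-like",
    "tannin-like",
    "condensed-hydrocarbon-like",
    "unsaturated-hydrocarbon-like",
)

INDEX_COLUMNS = ("dbe", "ai_mod", "nosc", "gfe")


# ---------------------------------------------------------------------------
# scalar index functions
# ---------------------------------------------------------------------------

def compute_dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents of a formula (requires c >= 1)."""
    if f.c < 1:
        raise ValidationError("DBE requires at least one carbon")
    return 1.0 + f.c - f.h / 2.0 + f.n / 2.0 + f.p / 2.0


def compute_ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index; degenerate cases return 0."""
    if f.c < 1:
        raise ValidationError("AI_Mod requires at least one carbon")
    numerator = 1.0 + f.c - f.o / 2.0 - f.s - f.h / 2.0
    denominator = f.c - f.o / 2.0 - f.s - f.n - f.p
    if denominator <= 0 or numerator < 0:
        return 0.0
    return numerator / denominator


def compute_nosc(f: MolecularFormula) -> float:
    """Nominal oxidation state of carbon of a neutral formula."""
    if f.c < 1:
        raise ValidationError("NOSC requires at least one carbon")
    return 4.0 - (4.0 * f.c + f.h - 3.0 * f.n - 2.0 * f.o + 5.0 * f.p - 2.0 * f.s) / f.c


def compute_gfe(nosc: float) -> float:
    """Standard Gibbs free energy of carbon oxidation, kJ (mol C)^-1."""
    return 60.3 - 28.5 * nosc


def compute_kendrick_defect(mass: float) -> float:
    """Kendrick mass defect on the CH2 repeat unit, in [0, 1)."""
    if mass <= 0:
        raise ValidationError("Kendrick defect requires a positive mass")
    kendrick_mass = mass * 14.0 / CH2_MASS
    return kendrick_mass - math.floor(kendrick_mass)


def is_aromatic(ai_mod: float) -> bool:
    return ai_mod > AROMATIC_THRESHOLD


def is_condensed_aromatic(ai_mod: float) -> bool:
    return ai_mod >= CONDENSED_AROMATIC_THRESHOLD


def assign_elemental_group(f: MolecularFormula) -> str:
    """Heteroatom-combination label; "other" outside the CHO-based set."""
    if f.c < 1 or f.h < 1 or f.o < 1:
        return "other"
    label = "CHO"
    if f.n > 0:
        label += "N"
    if f.s > 0:
        label += "S"
    if f.p > 0:
        label += "P"
    return label


# ---------------------------------------------------------------------------
# Van Krevelen boundaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VKRectangle:
    name: str
    oc_min: float
    oc_max: float
    hc_min: float
    hc_max: float
    oc_min_inclusive: bool = True
    oc_max_inclusive: bool = True
    hc_min_inclusive: bool = True
    hc_max_inclusive: bool = True

    def contains(self, oc: np.ndarray, hc: np.ndarray) -> np.ndarray:
        lo_oc = oc >= self.oc_min if self.oc_min_inclusive else oc > self.oc_min
        hi_oc = oc <= self.oc_max if self.oc_max_inclusive else oc < self.oc_max
        lo_hc = hc >= self.hc_min if self.hc_min_inclusive else hc > self.hc_min
        hi_hc = hc <= self.hc_max if self.hc_max_inclusive else hc < self.hc_max
        return lo_oc & hi_oc & lo_hc & hi_hc


class VKBoundarySet:
    """Ordered Van Krevelen class rectangles; first match wins."""

    def __init__(self, rectangles: list[VKRectangle]):
        if not rectangles:
            raise ConfigError("boundary table defines no classes")
        self.rectangles = list(rectangles)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VKBoundarySet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "classes" not in raw:
            raise ConfigError("boundary file must define a 'classes' list")
        rects = []
        for entry in raw["classes"]:
            for key in ("name", "oc_min", "oc_max", "hc_min", "hc_max"):
                if key not in entry:
                    raise ConfigError(f"boundary entry missing {key!r}: {entry}")
            if entry["oc_min"] > entry["oc_max"] or entry["hc_min"] > entry["hc_max"]:
                raise ConfigError(f"inverted bounds in boundary entry: {entry}")
            rects.append(VKRectangle(
                name=str(entry["name"]),
                oc_min=float(entry["oc_min"]), oc_max=float(entry["oc_max"]),
                hc_min=float(entry["hc_min"]), hc_max=float(entry["hc_max"]),
                oc_min_inclusive=bool(entry.get("oc_min_inclusive", True)),
                oc_max_inclusive=bool(entry.get("oc_max_inclusive", True)),
                hc_min_inclusive=bool(entry.get("hc_min_inclusive", True)),
                hc_max_inclusive=bool(entry.get("hc_max_inclusive", True)),
            ))
        return cls(rects)

    @property
    def class_names(self) -> list[str]:
        return [r.name for r in self.rectangles]

    def classify(self, oc: np.ndarray, hc: np.ndarray) -> np.ndarray:
        """Vectorized class labels for O:C / H:C arrays ("other" if no match)."""
        oc = np.asarray(oc, float)
        hc = np.asarray(hc, float)
        labels = np.full(oc.shape, "other", dtype=object)
        unassigned = np.ones(oc.shape, bool)
        for rect in self.rectangles:
            hit = unassigned & rect.contains(oc, hc)
            labels[hit] = rect.name
            unassigned &= ~hit
        return labels


def default_boundaries() -> VKBoundarySet:
    """The bundled default boundary table."""
    with resources.as_file(resources.files("riverchem.data") / "vk_boundaries.yaml") as p:
        return VKBoundarySet.from_yaml(p)


def assign_vk_class(f: MolecularFormula, boundaries: VKBoundarySet | None = None) -> str:
    """Van Krevelen class of one formula under a boundary table."""
    if f.c < 1:
        raise ValidationError("Van Krevelen classification requires at least one carbon")
    if boundaries is None:
        boundaries = default_boundaries()
    return str(boundaries.classify(np.array([f.o / f.c]), np.array([f.h / f.c]))[0])


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

def filter_peaks(table: PeakTable, mz_min: float = 200.0, mz_max: float = 900.0) -> PeakTable:
    """Keep peaks with mass in [mz_min, mz_max] (inclusive) and no 13C flag.

    The sample set is unchanged; an empty result is returned (with a
    warning), not raised.
    """
    if not mz_min < mz_max:
        raise ValidationError(f"mz_min must be < mz_max (got {mz_min}, {mz_max})")
    masses = table.masses
    keep = (masses >= mz_min) & (masses <= mz_max) & ~table.peaks["is_c13"].to_numpy(bool)
    if not keep.any():
        logger.warning("peak filter removed every peak (range %.1f-%.1f)", mz_min, mz_max)
    return table.subset_peaks(keep)


def peak_properties(table: PeakTable, boundaries: VKBoundarySet | None = None) -> pd.DataFrame:
    """Per-peak molecular properties, aligned row-wise with ``table``.

    Index columns are NaN and labels "other" for peaks without an
    assigned formula.
    """
    if boundaries is None:
        boundaries = default_boundaries()
    peaks = table.peaks
    c = peaks["c"].to_numpy(float)
    h = peaks["h"].to_numpy(float)
    n = peaks["n"].to_numpy(float)
    o = peaks["o"].to_numpy(float)
    s = peaks["s"].to_numpy(float)
    p = peaks["p"].to_numpy(float)
    assigned = table.has_formula

    with np.errstate(divide="ignore", invalid="ignore"):
        dbe = 1.0 + c - h / 2.0 + n / 2.0 + p / 2.0
        numerator = 1.0 + c - o / 2.0 - s - h / 2.0
        denominator = c - o / 2.0 - s - n - p
        ai = np.where((denominator > 0) & (numerator >= 0), numerator / denominator, 0.0)
        nosc = 4.0 - (4.0 * c + h - 3.0 * n - 2.0 * o + 5.0 * p - 2.0 * s) / c
        oc = o / c
        hc = h / c
    gfe = 60.3 - 28.5 * nosc

    kendrick_mass = table.masses * 14.0 / CH2_MASS
    kendrick_defect = kendrick_mass - np.floor(kendrick_mass)

    group = np.full(len(peaks), "other", dtype=object)
    in_cho = assigned & (o >= 1)
    labels = np.char.add(
        np.char.add(
            np.where(n > 0, "N", ""),
            np.where(s > 0, "S", ""),
        ),
        np.where(p > 0, "P", ""),
    )
    group[in_cho] = np.char.add("CHO", labels.astype(str))[in_cho]

    vk = np.full(len(peaks), "other", dtype=object)
    if assigned.any():
        vk[assigned] = boundaries.classify(oc[assigned], hc[assigned])

    out = pd.DataFrame({
        "mass": table.masses,
        "has_formula": assigned,
        "dbe": np.where(assigned, dbe, np.nan),
        "ai_mod": np.where(assigned, ai, np.nan),
        "nosc": np.where(assigned, nosc, np.nan),
        "gfe": np.where(assigned, gfe, np.nan),
        "kendrick_defect": kendrick_defect,
        "elemental_group": group,
        "vk_class": vk,
    })
    out["aromatic"] = out["ai_mod"] > AROMATIC_THRESHOLD
    out["condensed_aromatic"] = out["ai_mod"] >= CONDENSED_AROMATIC_THRESHOLD
    return out


def _abundance_block(labels: np.ndarray, presence: np.ndarray, names: tuple[str, ...], prefix: str) -> pd.DataFrame:
    """Per-sample relative abundance (count fraction) of each label."""
    columns = list(names) + ["other"]
    onehot = np.stack([(labels == name) for name in columns], axis=1).astype(float)
    counts = presence.T @ onehot  # samples x labels
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(frac, columns=[f"{prefix}_{name}" for name in columns])


def summarize_samples(
    table: PeakTable,
    props: pd.DataFrame | None = None,
    boundaries: VKBoundarySet | None = None,
    intensity_weighted: bool = False,
) -> pd.DataFrame:
    """Per-sample summary over detected, formula-assigned peaks.

    One row per sample: mean DBE/AI_Mod/NOSC/GFE, richness (number of
    formula-assigned peaks detected), and relative abundances of each
    elemental group and Van Krevelen class. Samples detecting no
    formula-assigned peak get richness 0 and NaN means.

    Means are unweighted by default, matching the presence/absence
    philosophy of the downstream statistics; ``intensity_weighted=True``
    weights by detection intensity instead.
    """
    if props is None:
        props = peak_properties(table, boundaries)
    if len(props) != table.n_peaks:
        raise ValidationError("properties frame does not align with the peak table")
    assigned = props["has_formula"].to_numpy(bool)
    presence = table.presence[assigned]
    weights = presence.astype(float)
    if intensity_weighted:
        weights = table.detections.to_numpy(float)[assigned] * presence

    richness = presence.sum(axis=0)
    index_vals = props.loc[assigned, list(INDEX_COLUMNS)].to_numpy(float)
    wsum = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (weights.T @ index_vals) / wsum[:, None]
    means[wsum == 0] = np.nan

    out = pd.DataFrame(means, columns=[f"mean_{c}" for c in INDEX_COLUMNS])
    out.insert(0, "sample_id", table.sample_ids)
    out.insert(1, "richness", richness.astype(int))
    groups = _abundance_block(
        props["elemental_group"].to_numpy(object)[assigned], presence, ELEMENTAL_GROUPS, "group")
    classes = _abundance_block(
        props["vk_class"].to_numpy(object)[assigned], presence, VK_CLASSES, "class")
    out = pd.concat([out, groups, classes], axis=1)
    return out.set_index("sample_id")


def summarize_sample(
    table: PeakTable,
    props: pd.DataFrame,
    sample_id: str,
) -> pd.Series:
    """Summary row for a single sample (see :func:`summarize_samples`)."""
    if sample_id not in table.sample_ids:
        raise ValidationError(f"unknown sample id: {sample_id}")
    return summarize_samples(table.subset_samples([sample_id]), props).loc[sample_id]
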