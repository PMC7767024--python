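"""Reading, writing and validation of the study's tabular formats.

Three tables flow through the pipeline:

* a **peak table** (one row per FTICR-MS peak: neutral monoisotopic mass,
  element counts, a 13C-isotopologue flag, and one intensity column per
  sample), in either the wide "formularity" dialect or a long
  (mass, sample, intensity) dialect;
* a **sample metadata** table (sample id, site id, environment,
  replicate, latitude/longitude);
* a **biochemical transformation reference list** (name, mass,
  optional composition).

All files are UTF-8 CSV with a decimal point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .formulas import PROTON_MASS, MolecularFormula

logger = logging.getLogger(__name__)

#: Peaks whose masses differ by less than this (Da) are treated as the
#: same peak and merged (union of detections). Far tighter than the
#: instrument's alignment tolerance so no genuinely distinct peaks merge.
MASS_MERGE_TOL = 1e-6

ELEMENT_COLUMNS = ["C", "H", "O", "N", "S", "P"]
ENVIRONMENTS = ("surface_water", "sediment")


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata of one analytical sample."""

    sample_id: str
    site_id: str
    environment: str
    replicate: str
    latitude: float
    longitude: float


@dataclass(frozen=True)
class TransformationRef:
    """One named reference mass for mass-difference transformation inference."""

    name: str
    mass: float
    contains_n: bool = False
    contains_s: bool = False
    contains_p: bool = False
    composition: str | None = None


class PeakTable:
    """Peaks x samples detection matrix keyed by ascending neutral mass.

    Parameters
    ----------
    peaks : DataFrame with columns ``mass`` (float, strictly increasing),
        ``c h n o s p`` (int element counts; all zero when no formula was
        assigned) and ``is_c13`` (bool isotopologue flag).
    detections : DataFrame aligned row-wise with ``peaks``; one column per
        sample holding intensities (0 = not detected).
    """

    def __init__(self, peaks: pd.DataFrame, detections: pd.DataFrame):
        peaks = peaks.reset_index(drop=True)
        detections = detections.reset_index(drop=True)
        required = {"mass", "c", "h", "n", "o", "s", "p", "is_c13"}
        missing = required - set(peaks.columns)
        if missing:
            raise ValidationError(f"peaks frame missing columns: {sorted(missing)}")
        if len(peaks) != len(detections):
            raise ValidationError("peaks and detections row counts differ")
        if len(detections.columns) != len(set(detections.columns)):
            raise ValidationError("duplicate sample ids in detection matrix")
        masses = peaks["mass"].to_numpy(float)
        if len(masses) > 1 and not np.all(np.diff(masses) > 0):
            raise ValidationError("peak masses must be strictly increasing; use from_frames() to sort/merge")
        if len(masses) and masses.min() <= 0:
            raise ValidationError("peak masses must be positive")
        self.peaks = peaks
        self.detections = detections.astype(float)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_frames(cls, peaks: pd.DataFrame, detections: pd.DataFrame) -> "PeakTable":
        """Build a table from unsorted frames, merging duplicate masses.

        Rows whose masses agree within :data:`MASS_MERGE_TOL` are merged:
        the first row's mass/formula/flag is kept and detections take the
        union (element-wise maximum).
        """
        order = np.argsort(peaks["mass"].to_numpy(float), kind="stable")
        peaks = peaks.iloc[order].reset_index(drop=True)
        detections = detections.iloc[order].reset_index(drop=True)
        masses = peaks["mass"].to_numpy(float)
        if len(masses) > 1:
            new_group = np.concatenate([[True], np.diff(masses) > MASS_MERGE_TOL])
        else:
            new_group = np.ones(len(masses), bool)
        group = np.cumsum(new_group) - 1
        if len(masses) and group[-1] + 1 < len(masses):
            n_merged = len(masses) - (group[-1] + 1)
            logger.warning("merged %d duplicate-mass peak rows (tol %.0e Da)", n_merged, MASS_MERGE_TOL)
            keep_first = np.flatnonzero(new_group)
            merged_peaks = peaks.iloc[keep_first].reset_index(drop=True)
            merged_det = detections.groupby(group).max().reset_index(drop=True)
            return cls(merged_peaks, merged_det)
        return cls(peaks, detections)

    # -- basic accessors ------------------------------------------------

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.detections.columns)

    @property
    def masses(self) -> np.ndarray:
        return self.peaks["mass"].to_numpy(float)

    @property
    def has_formula(self) -> np.ndarray:
        """Boolean mask of peaks with an assigned molecular formula."""
        return (self.peaks["c"].to_numpy() >= 1) & (self.peaks["h"].to_numpy() >= 1)

    @property
    def presence(self) -> np.ndarray:
        """Boolean peaks x samples detection matrix."""
        return self.detections.to_numpy(float) > 0

    def formula_at(self, index: int) -> MolecularFormula | None:
        row = self.peaks.iloc[index]
        if row["c"] >= 1 and row["h"] >= 1:
            return MolecularFormula(
                c=int(row["c"]), h=int(row["h"]), n=int(row["n"]),
                o=int(row["o"]), s=int(row["s"]), p=int(row["p"]),
            )
        return None

    def subset_peaks(self, mask: np.ndarray) -> "PeakTable":
        mask = np.asarray(mask, bool)
        return PeakTable(self.peaks.loc[mask], self.detections.loc[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakTable":
        missing = [s for s in sample_ids if s not in self.detections.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return PeakTable(self.peaks, self.detections.loc[:, list(sample_ids)])

    def sample_masses(self, sample_id: str) -> np.ndarray:
        """Ascending masses of the peaks detected in one sample."""
        if sample_id not in self.detections.columns:
            raise ValidationError(f"unknown sample id: {sample_id}")
        detected = self.detections[sample_id].to_numpy(float) > 0
        return self.masses[detected]

    def equals(self, other: "PeakTable", mass_tol: float = MASS_MERGE_TOL) -> bool:
        if self.n_peaks != other.n_peaks or self.sample_ids != other.sample_ids:
            return False
        if not np.allclose(self.masses, other.masses, rtol=0, atol=mass_tol):
            return False
        cols = ["c", "h", "n", "o", "s", "p", "is_c13"]
        if not self.peaks[cols].reset_index(drop=True).equals(other.peaks[cols].reset_index(drop=True)):
            return False
        return bool(np.array_equal(self.presence, other.presence))

    # -- writing ---------------------------------------------------------

    def write(self, path: str | Path, dialect: str = "formularity") -> None:
        write_peak_table(self, path, dialect=dialect)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

_PEAK_META_COLS = ["Mass", "C", "H", "O", "N", "S", "P", "C13"]


def _finalize_peaks(raw: pd.DataFrame, mass_mode: str) -> pd.DataFrame:
    mass = pd.to_numeric(raw["Mass"], errors="coerce")
    bad = mass.isna() & raw["Mass"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header line + 1-based
        raise FormatError(f"non-numeric mass at line {line}: {raw['Mass'][bad.idxmax()]!r}")
    if mass.isna().any():
        line = int(mass.isna().idxmax()) + 2
        raise FormatError(f"missing mass at line {line}")
    if mass_mode == "mz_negative":
        mass = mass + PROTON_MASS
    elif mass_mode != "neutral":
        raise FormatError(f"unknown mass_mode: {mass_mode!r}")
    if (mass <= 0).any():
        raise FormatError("non-positive mass in peak table")
    out = pd.DataFrame({"mass": mass.astype(float)})
    for col in ELEMENT_COLUMNS:
        counts = pd.to_numeric(raw[col], errors="coerce").fillna(0)
        if (counts < 0).any():
            raise FormatError(f"negative element count in column {col}")
        out[col.lower()] = counts.astype(int)
    c13 = pd.to_numeric(raw.get("C13", 0), errors="coerce").fillna(0)
    out["is_c13"] = c13.astype(float) > 0
    return out


def read_peak_table(
    path: str | Path,
    dialect: str = "formularity",
    mass_mode: str = "neutral",
) -> PeakTable:
    """Read a peak table.

    ``dialect="formularity"`` expects the wide layout ``Mass, C, H, O, N,
    S, P[, C13]`` followed by one intensity column per sample;
    ``dialect="long"`` expects ``Mass, Sample, Intensity`` triplets with
    optional per-row element-count columns.

    ``mass_mode="mz_negative"`` converts negative-mode m/z values to
    neutral masses by adding the mass of a proton.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, comment="#")
    if dialect == "formularity":
        required = ["Mass"] + ELEMENT_COLUMNS
        for col in required:
            if col not in raw.columns:
                raise FormatError(f"missing required column: {col}")
        sample_cols = [c for c in raw.columns if c not in _PEAK_META_COLS]
        if not sample_cols:
            raise FormatError("peak table has no sample columns")
        peaks = _finalize_peaks(raw, mass_mode)
        detections = raw[sample_cols].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    elif dialect == "long":
        for col in ("Mass", "Sample", "Intensity"):
            if col not in raw.columns:
                raise FormatError(f"missing required column: {col}")
        for col in ELEMENT_COLUMNS + ["C13"]:
            if col not in raw.columns:
                raw[col] = 0
        meta = raw.drop_duplicates(subset="Mass", keep="first").reset_index(drop=True)
        peaks = _finalize_peaks(meta, mass_mode)
        wide = raw.pivot_table(
            index="Mass", columns="Sample", values="Intensity", aggfunc="max", fill_value=0.0
        )
        wide = wide.reindex(meta["Mass"].to_numpy()).fillna(0.0)
        detections = wide.reset_index(drop=True)
        detections.columns = [str(c) for c in detections.columns]
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")
    return PeakTable.from_frames(peaks, detections)


def write_peak_table(table: PeakTable, path: str | Path, dialect: str = "formularity") -> None:
    """Write a peak table in one of the supported dialects."""
    path = Path(path)
    peaks = table.peaks
    if dialect == "formularity":
        out = pd.DataFrame({
            "Mass": peaks["mass"].map(lambda m: f"{m:.7f}"),
            "C": peaks["c"], "H": peaks["h"], "O": peaks["o"],
            "N": peaks["n"], "S": peaks["s"], "P": peaks["p"],
            "C13": peaks["is_c13"].astype(int),
        })
        for sample in table.sample_ids:
            out[sample] = table.detections[sample]
        out.to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        presence = table.detections.to_numpy(float)
        for j, sample in enumerate(table.sample_ids):
            detected = np.flatnonzero(presence[:, j] > 0)
            block = peaks.iloc[detected]
            rows.append(pd.DataFrame({
                "Mass": block["mass"].map(lambda m: f"{m:.7f}"),
                "Sample": sample,
                "Intensity": presence[detected, j],
                "C": block["c"], "H": block["h"], "O": block["o"],
                "N": block["n"], "S": block["s"], "P": block["p"],
                "C13": block["is_c13"].astype(int),
            }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_METADATA_COLS = ["Sample_ID", "Site_ID", "Environment", "Replicate", "Latitude", "Longitude"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata table.

    Returns a DataFrame with columns ``sample_id, site_id, environment,
    replicate, latitude, longitude``; one row per sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, comment="#")
    for col in _METADATA_COLS:
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col}")
    out = pd.DataFrame({
        "sample_id": raw["Sample_ID"].astype(str),
        "site_id": raw["Site_ID"].astype(str),
        "environment": raw["Environment"].astype(str).str.strip().str.lower(),
        "replicate": raw["Replicate"].astype(str),
        "latitude": pd.to_numeric(raw["Latitude"], errors="coerce"),
        "longitude": pd.to_numeric(raw["Longitude"], errors="coerce"),
    })
    dup = out["sample_id"].duplicated()
    if dup.any():
        raise ValidationError(f"duplicate sample_id: {out.loc[dup, 'sample_id'].iloc[0]!r}")
    bad_env = ~out["environment"].isin(ENVIRONMENTS)
    if bad_env.any():
        raise ValidationError(
            f"unknown environment label {out.loc[bad_env, 'environment'].iloc[0]!r}; "
            f"expected one of {ENVIRONMENTS}"
        )
    if out["latitude"].isna().any() or out["latitude"].abs().gt(90).any():
        raise ValidationError("latitude outside [-90, 90]")
    if out["longitude"].isna().any() or out["longitude"].abs().gt(180).any():
        raise ValidationError("longitude outside [-180, 180]")
    return out


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        "Sample_ID": metadata["sample_id"],
        "Site_ID": metadata["site_id"],
        "Environment": metadata["environment"],
        "Replicate": metadata["replicate"],
        "Latitude": metadata["latitude"],
        "Longitude": metadata["longitude"],
    })
    out.to_csv(path, index=False)


def metadata_records(metadata: pd.DataFrame) -> list[SampleMetadata]:
    """The metadata frame as a list of :class:`SampleMetadata` records."""
    return [
        SampleMetadata(
            sample_id=row.sample_id, site_id=row.site_id, environment=row.environment,
            replicate=row.replicate, latitude=float(row.latitude), longitude=float(row.longitude),
        )
        for row in metadata.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# transformation reference lists
# ---------------------------------------------------------------------------

def _flags_from_composition(text: str) -> tuple[bool, bool, bool]:
    f = MolecularFormula.from_string(text)
    return f.n > 0, f.s > 0, f.p > 0


def read_transformation_list(
    path: str | Path,
    name_rules: dict[str, dict[str, bool]] | None = None,
) -> pd.DataFrame:
    """Read a transformation reference list (``Name, Mass[, Composition]``).

    Compositional category flags (``contains_n/s/p``) come from the
    composition string when present, otherwise from substring
    ``name_rules`` (pattern -> flag dict), otherwise all false.
    Duplicate (name, mass) rows are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, comment="#")
    for col in ("Name", "Mass"):
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col}")
    mass = pd.to_numeric(raw["Mass"], errors="coerce")
    if mass.isna().any():
        raise FormatError("non-numeric mass in transformation list")
    if (mass <= 0).any():
        raise ValidationError("non-positive transformation mass")
    out = pd.DataFrame({
        "name": raw["Name"].astype(str),
        "mass": mass.astype(float),
        "composition": raw["Composition"].astype(str) if "Composition" in raw.columns else None,
    })
    dup = out.duplicated(subset=["name", "mass"])
    if dup.any():
        logger.warning("dropping %d duplicate (name, mass) transformation entries", int(dup.sum()))
        out = out.loc[~dup].reset_index(drop=True)

    flags = np.zeros((len(out), 3), bool)
    for i, row in enumerate(out.itertuples(index=False)):
        comp = row.composition
        if isinstance(comp, str) and comp and comp.lower() != "nan":
            flags[i] = _flags_from_composition(comp)
        elif name_rules:
            for pattern, rule in name_rules.items():
                if pattern in row.name:
                    flags[i] = (
                        rule.get("contains_n", False),
                        rule.get("contains_s", False),
                        rule.get("contains_p", False),
                    )
                    break
    out["contains_n"], out["contains_s"], out["contains_p"] = flags.T
    return out


def transformation_records(refs: pd.DataFrame) -> list[TransformationRef]:
    return [
        TransformationRef(
            name=row.name, mass=float(row.mass),
            contains_n=bool(row.contains_n), contains_s=bool(row.contains_s),
            contains_p=bool(row.contains_p),
            composition=row.composition if isinstance(row.composition, str) else None,
        )
        for row in refs.itertuples(index=False)
    ]


def load_bundled_transformations() -> pd.DataFrame:
    """The package's bundled 1255-entry transformation reference list.

    The list is synthetic: it is generated by :mod:`riverchem.refbuild`
    from named biochemical moieties and their combinations, matching the
    size and worked-example anchor masses of the lists used for
    mass-difference transformation analysis of natural organic matter.
    """
    with resources.as_file(
        resources.files("riverchem.data") / "transformations_synthetic_1255.csv"
    ) as p:
        return read_transformation_list(p)
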