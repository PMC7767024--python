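"""Biochemical-transformation inference from pairwise peak mass differences.

For every pair of peaks detected in a sample, the unsigned mass
difference is compared against a reference list of transformation masses
(common gains/losses: amino acids, sugars, phosphate, ...). A pair whose
difference matches a reference mass within tolerance (default 1 ppm of
the reference mass) is recorded as a putative gain or loss of that
moiety. Formula assignment is NOT required: matching runs on all
retained peak masses.

Matched transformations are grouped into four compositional categories
-- CHO-only, N-containing, S-containing and P-containing -- and
summarized per sample as counts and relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import mannwhitney_fdr

logger = logging.getLogger(__name__)

CATEGORIES = ("CHO", "N", "S", "P")

_MATCH_COLUMNS = ["i", "j", "ref_index", "name", "low_mass", "high_mass", "observed_delta", "error_ppm"]


def _check_masses(masses: np.ndarray) -> np.ndarray:
    masses = np.asarray(masses, float)
    if masses.ndim != 1:
        raise ValidationError("masses must be a 1-D array")
    if len(masses) > 1 and not np.all(np.diff(masses) > 0):
        raise ValidationError("masses must be sorted ascending and deduplicated")
    return masses


def _ref_arrays(refs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ref_mass = refs["mass"].to_numpy(float)
    ref_name = refs["name"].to_numpy(object)
    if (ref_mass <= 0).any():
        raise ValidationError("transformation reference masses must be positive")
    return ref_mass, ref_name


def _tolerance(ref_mass: np.ndarray, high_mass: np.ndarray, tolerance_ppm: float, basis: str) -> np.ndarray:
    if basis == "ref":
        return tolerance_ppm * 1e-6 * ref_mass
    if basis == "pair":
        return tolerance_ppm * 1e-6 * high_mass
    raise ValidationError(f"unknown tolerance basis: {basis!r}")


def _as_frame(i, j, ref_idx, masses, ref_mass, ref_name) -> pd.DataFrame:
    low = masses[i]
    high = masses[j]
    delta = high - low
    rmass = ref_mass[ref_idx]
    return pd.DataFrame({
        "i": i, "j": j, "ref_index": ref_idx,
        "name": ref_name[ref_idx],
        "low_mass": low, "high_mass": high,
        "observed_delta": delta,
        "error_ppm": (delta - rmass) / rmass * 1e6,
    }, columns=_MATCH_COLUMNS)


def match_transformations(
    masses: np.ndarray,
    refs: pd.DataFrame,
    tolerance_ppm: float = 1.0,
    basis: str = "ref",
) -> pd.DataFrame:
    """Match pairwise mass differences against a reference list.

    Parameters
    ----------
    masses : ascending, deduplicated neutral masses (Da) of one sample.
    refs : reference list frame (``name``, ``mass``, category flags).
    tolerance_ppm : matching tolerance; by default measured relative to
        the reference transformation mass (``basis="ref"``), optionally
        relative to the heavier peak of the pair (``basis="pair"``).

    Returns every qualifying (low peak, high peak, reference) triple; a
    single pair may match several references. Binary search of
    ``m_i + ref_mass`` over the sorted mass list makes this subquadratic
    in practice while the final acceptance test is the same closed-form
    inequality the exhaustive oracle uses, so the output is identical.
    """
    masses = _check_masses(masses)
    if tolerance_ppm <= 0:
        raise ValidationError("tolerance_ppm must be positive")
    if len(masses) < 2 or len(refs) == 0:
        return pd.DataFrame(columns=_MATCH_COLUMNS)
    ref_mass, ref_name = _ref_arrays(refs)
    n = len(masses)
    k = len(ref_mass)

    # Search window, padded so that float re-association between
    # (m_j - m_i) - r and m_j - (m_i + r) can never drop a boundary hit.
    window = _tolerance(ref_mass, np.full(k, masses[-1]), tolerance_ppm, basis)
    pad = window * (1.0 + 1e-9) + 1e-9
    targets = masses[None, :] + ref_mass[:, None]            # k x n
    lo = np.searchsorted(masses, (targets - pad[:, None]).ravel(), side="left")
    hi = np.searchsorted(masses, (targets + pad[:, None]).ravel(), side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=_MATCH_COLUMNS)
    flat = np.repeat(np.arange(k * n), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    j = lo[flat] + offsets
    ref_idx = flat // n
    i = flat % n

    keep = j > i
    i, j, ref_idx = i[keep], j[keep], ref_idx[keep]
    delta = masses[j] - masses[i]
    tol = _tolerance(ref_mass[ref_idx], masses[j], tolerance_ppm, basis)
    keep = np.abs(delta - ref_mass[ref_idx]) <= tol
    return _as_frame(i[keep], j[keep], ref_idx[keep], masses, ref_mass, ref_name)


def match_transformations_bruteforce(
    masses: np.ndarray,
    refs: pd.DataFrame,
    tolerance_ppm: float = 1.0,
    basis: str = "ref",
    chunk: int = 256,
) -> pd.DataFrame:
    """Exhaustive O(n^2 k) enumeration over all peak pairs and references.

    Oracle counterpart of :func:`match_transformations`: every pair
    difference is tested against every reference mass with the same
    acceptance inequality. Intended for validation at small n.
    """
    masses = _check_masses(masses)
    if tolerance_ppm <= 0:
        raise ValidationError("tolerance_ppm must be positive")
    if len(masses) < 2 or len(refs) == 0:
        return pd.DataFrame(columns=_MATCH_COLUMNS)
    ref_mass, ref_name = _ref_arrays(refs)
    iu, ju = np.triu_indices(len(masses), k=1)
    delta = masses[ju] - masses[iu]
    parts = []
    for start in range(0, len(ref_mass), chunk):
        block = ref_mass[start:start + chunk]
        if basis == "ref":
            tol = tolerance_ppm * 1e-6 * block[None, :]
        else:
            tol = tolerance_ppm * 1e-6 * masses[ju][:, None]
        hit = np.abs(delta[:, None] - block[None, :]) <= tol
        pair_idx, ref_off = np.nonzero(hit)
        if len(pair_idx):
            parts.append((iu[pair_idx], ju[pair_idx], ref_off + start))
    if not parts:
        return pd.DataFrame(columns=_MATCH_COLUMNS)
    i = np.concatenate([p[0] for p in parts])
    j = np.concatenate([p[1] for p in parts])
    ridx = np.concatenate([p[2] for p in parts])
    order = np.lexsort((ridx, j, i))
    return _as_frame(i[order], j[order], ridx[order], masses, ref_mass, ref_name)


def match_keys(matches: pd.DataFrame) -> set[tuple[int, int, int]]:
    """The (i, j, ref_index) identity set of a match frame."""
    return set(zip(matches["i"].astype(int), matches["j"].astype(int), matches["ref_index"].astype(int)))


# ---------------------------------------------------------------------------
# per-sample profiles
# ---------------------------------------------------------------------------

@dataclass
class TransformationProfile:
    """Counts and compositional-category abundances for one sample.

    A reference containing several heteroatoms counts toward every
    matching heteroatom category (multi-membership), so category
    abundances sum to exactly 1 only when each matched reference belongs
    to a single category; an exclusive mode (priority N > S > P) always
    sums to 1.
    """

    total: int
    ref_counts: pd.Series
    category_counts: pd.Series = field(default_factory=lambda: pd.Series(0, index=list(CATEGORIES)))

    @property
    def category_abundance(self) -> pd.Series:
        if self.total == 0:
            return pd.Series(np.nan, index=list(CATEGORIES))
        return self.category_counts / self.total


def profile_sample(
    matches: pd.DataFrame,
    refs: pd.DataFrame,
    mode: str = "multi",
) -> TransformationProfile:
    """Summarize one sample's matches into a category profile.

    ``mode="multi"`` (default) increments every heteroatom category a
    reference contains; ``mode="exclusive"`` assigns each match a single
    category with priority N > S > P.
    """
    if mode not in ("multi", "exclusive"):
        raise ValidationError(f"unknown profile mode: {mode!r}")
    total = len(matches)
    ref_counts = matches["name"].value_counts() if total else pd.Series(dtype=int)
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    if total:
        flags = refs.loc[matches["ref_index"].to_numpy(int), ["contains_n", "contains_s", "contains_p"]]
        has_n = flags["contains_n"].to_numpy(bool)
        has_s = flags["contains_s"].to_numpy(bool)
        has_p = flags["contains_p"].to_numpy(bool)
        if mode == "multi":
            counts["N"] = int(has_n.sum())
            counts["S"] = int(has_s.sum())
            counts["P"] = int(has_p.sum())
        else:
            counts["N"] = int(has_n.sum())
            counts["S"] = int((~has_n & has_s).sum())
            counts["P"] = int((~has_n & ~has_s & has_p).sum())
        counts["CHO"] = int((~has_n & ~has_s & ~has_p).sum())
    return TransformationProfile(total=total, ref_counts=ref_counts, category_counts=counts)


def profile_mass_sets(
    mass_sets: dict[str, np.ndarray],
    refs: pd.DataFrame,
    tolerance_ppm: float = 1.0,
    basis: str = "ref",
    mode: str = "multi",
) -> pd.DataFrame:
    """Match and profile several detected-mass sets (samples or sites).

    Returns one row per set id: total match count, per-category counts
    (``count_*``) and relative abundances (``abund_*``).
    """
    rows = {}
    for set_id, masses in mass_sets.items():
        matches = match_transformations(masses, refs, tolerance_ppm=tolerance_ppm, basis=basis)
        profile = profile_sample(matches, refs, mode=mode)
        row = {"total": profile.total}
        for cat in CATEGORIES:
            row[f"count_{cat}"] = profile.category_counts[cat]
            row[f"abund_{cat}"] = profile.category_abundance[cat]
        rows[set_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def profile_table(table, refs: pd.DataFrame, tolerance_ppm: float = 1.0,
                  basis: str = "ref", mode: str = "multi") -> pd.DataFrame:
    """Per-sample transformation profiles for a :class:`~riverchem.io.PeakTable`."""
    mass_sets = {sid: table.sample_masses(sid) for sid in table.sample_ids}
    return profile_mass_sets(mass_sets, refs, tolerance_ppm=tolerance_ppm, basis=basis, mode=mode)


def compare_profiles(profiles: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-group comparison of the four category abundances.

    One two-sided Mann-Whitney U test per category, Benjamini-Hochberg
    adjusted across the four-category family.
    """
    groups = groups.reindex(profiles.index)
    for label, count in groups.value_counts().items():
        if count < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 samples")
    data = profiles[[f"abund_{cat}" for cat in CATEGORIES]]
    return mannwhitney_fdr(data, groups)
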