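"""Site-level aggregation and the CONUS East/West comparison.

FTICR-MS replicates are imperfectly reproducible, so a metabolite is
considered present at a site if it is detected in ANY replicate of that
site/environment combination (replicate union). Site profiles (mean
indices, group/class abundances, richness) are then compared between
sites east and west of the Mississippi River, using the longitude of
St. Louis, Missouri as the dividing meridian.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chemistry import ELEMENTAL_GROUPS, INDEX_COLUMNS, VK_CLASSES, summarize_samples
from .errors import ValidationError
from .io import PeakTable
from .stats import mannwhitney_fdr

logger = logging.getLogger(__name__)

#: Longitude of the Mississippi River at St. Louis, Missouri (decimal
#: degrees, west negative): the East/West dividing meridian.
EAST_WEST_THRESHOLD = -90.1994

#: Contiguous-US bounding box used to restrict the spatial comparison.
CONUS_BOX = {"lat_min": 24.0, "lat_max": 50.0, "lon_min": -125.0, "lon_max": -66.5}

#: Metric families adjusted together (one BH family per output table).
METRIC_FAMILIES = {
    "indices": ["richness"] + [f"mean_{c}" for c in INDEX_COLUMNS],
    "elemental_groups": [f"group_{g}" for g in ELEMENTAL_GROUPS] + ["group_other"],
    "vk_classes": [f"class_{c}" for c in VK_CLASSES] + ["class_other"],
}


def merge_replicates(table: PeakTable, metadata: pd.DataFrame) -> tuple[PeakTable, pd.DataFrame]:
    """Union-merge replicates into one column per site x environment.

    Returns the site-level table (sample ids ``"<site>|<environment>"``)
    and a site metadata frame (site_id, environment, latitude, longitude,
    n_replicates). Latitude/longitude are replicate means.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"sample without metadata: {missing[0]!r}")
    presence = table.presence
    site_cols = {}
    site_rows = []
    keys = meta.loc[table.sample_ids, ["site_id", "environment"]]
    for (site, env), block in keys.groupby(["site_id", "environment"], sort=True):
        cols = [table.sample_ids.index(s) for s in block.index]
        site_key = f"{site}|{env}"
        site_cols[site_key] = presence[:, cols].any(axis=1).astype(float)
        rows = meta.loc[block.index]
        site_rows.append({
            "site_key": site_key, "site_id": site, "environment": env,
            "latitude": float(rows["latitude"].mean()),
            "longitude": float(rows["longitude"].mean()),
            "n_replicates": len(cols),
        })
    detections = pd.DataFrame(site_cols)
    site_meta = pd.DataFrame(site_rows).set_index("site_key")
    return PeakTable(table.peaks, detections), site_meta


def site_summaries(
    site_table: PeakTable,
    site_meta: pd.DataFrame,
    props: pd.DataFrame | None = None,
    boundaries=None,
) -> pd.DataFrame:
    """One profile row per site x environment: summary metrics + location."""
    summary = summarize_samples(site_table, props=props, boundaries=boundaries)
    return site_meta.join(summary)


def split_east_west(profiles: pd.DataFrame, threshold: float = EAST_WEST_THRESHOLD) -> pd.DataFrame:
    """Label each profile East (longitude > threshold) or West.

    Sites exactly on the meridian go West (strict inequality). Profiles
    without a longitude are dropped with a warning.
    """
    out = profiles.copy()
    missing = out["longitude"].isna()
    if missing.any():
        logger.warning("excluding %d profiles without longitude", int(missing.sum()))
        out = out.loc[~missing]
    out["region"] = np.where(out["longitude"] > threshold, "East", "West")
    return out


def conus_filter(profiles: pd.DataFrame, box: dict | None = None) -> pd.DataFrame:
    """Restrict profiles to the contiguous-US bounding box."""
    box = box or CONUS_BOX
    keep = (
        profiles["latitude"].between(box["lat_min"], box["lat_max"])
        & profiles["longitude"].between(box["lon_min"], box["lon_max"])
    )
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("excluding %d non-CONUS profiles", dropped)
    return profiles.loc[keep]


def east_west_compare(
    profiles: pd.DataFrame,
    families: dict[str, list[str]] | None = None,
    threshold: float = EAST_WEST_THRESHOLD,
    box: dict | None = None,
) -> pd.DataFrame:
    """Per-environment East vs. West comparisons, one BH family at a time.

    ``profiles`` is the site-summary frame (one row per site x
    environment, with latitude/longitude). Returns the comparison table
    with ``environment`` and ``family`` columns added.
    """
    families = families or METRIC_FAMILIES
    labelled = split_east_west(conus_filter(profiles, box), threshold)
    results = []
    for env, env_block in labelled.groupby("environment", sort=True):
        counts = env_block["region"].value_counts()
        for side in ("East", "West"):
            if counts.get(side, 0) < 2:
                raise ValidationError(
                    f"fewer than 2 {side} sites in environment {env!r}")
        for family, columns in families.items():
            present = [c for c in columns if c in env_block.columns]
            comp = mannwhitney_fdr(env_block[present], env_block["region"],
                                   group_order=("East", "West"))
            comp.insert(0, "environment", env)
            comp.insert(1, "family", family)
            results.append(comp)
    return pd.concat(results, ignore_index=True)
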