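"""Multivariate and univariate chemodiversity comparisons.

The pipeline compares surface-water and sediment metabolomes on
presence/absence data: PCA on mean-centred detection matrices, Euclidean
PERMANOVA (McArdle-Anderson sums-of-squares partition with permutation
p-values), beta-dispersion (distance to the group centroid), and
two-sided Mann-Whitney U tests with Benjamini-Hochberg FDR adjustment
for families of univariate metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import PeakTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# presence/absence + distances
# ---------------------------------------------------------------------------

def presence_absence(table: PeakTable) -> pd.DataFrame:
    """Samples x peaks 0/1 matrix; intensities are discarded."""
    if table.n_peaks == 0:
        raise ValidationError("peak table is empty")
    matrix = (table.detections.to_numpy(float) > 0).astype(float).T
    return pd.DataFrame(matrix, index=table.sample_ids, columns=table.masses)


def euclidean_distance(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Euclidean distance between sample rows."""
    values = np.asarray(matrix, float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(values))
    return pd.DataFrame(squareform(pdist(values, metric="euclidean")), index=index, columns=index)


def _check_distance(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(dist, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValidationError("distance matrix must have a zero diagonal")
    return d


def _group_codes(groups) -> tuple[np.ndarray, list]:
    labels = np.asarray(groups)
    names = sorted(pd.unique(labels).tolist())
    codes = np.searchsorted(np.array(names, dtype=object), labels)
    return codes.astype(int), names


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCA scores, per-component variance proportions and peak loadings."""

    scores: pd.DataFrame               # samples x components
    proportion_variance: np.ndarray    # per component, non-increasing
    loadings: pd.DataFrame             # peaks x components


def pca(matrix: pd.DataFrame) -> OrdinationResult:
    """PCA of a samples x peaks matrix (columns centred, NOT scaled)."""
    values = np.asarray(matrix, float)
    n, m = values.shape
    if n < 2 or m < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 peaks")
    total_var = np.var(values, axis=0, ddof=1).sum()
    n_comp = min(n - 1, m)
    if total_var <= 0:
        logger.warning("PCA input has zero variance; all components are degenerate")
        comp_names = [f"PC{i+1}" for i in range(n_comp)]
        scores = pd.DataFrame(np.zeros((n, n_comp)), index=matrix.index, columns=comp_names)
        loadings = pd.DataFrame(np.zeros((m, n_comp)), index=matrix.columns, columns=comp_names)
        return OrdinationResult(scores, np.zeros(n_comp), loadings)
    model = PCA(n_components=n_comp, svd_solver="full")
    transformed = model.fit_transform(values)
    comp_names = [f"PC{i+1}" for i in range(n_comp)]
    scores = pd.DataFrame(transformed, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(model.components_.T, index=matrix.columns, columns=comp_names)
    return OrdinationResult(scores, model.explained_variance_ratio_, loadings)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _within_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ssw = 0.0
    for g in range(n_groups):
        members = codes == g
        ssw += d2[np.ix_(members, members)].sum() / (2.0 * members.sum())
    return ssw


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F follows the McArdle-Anderson partition of total and
    within-group sums of squared distances; the p-value is
    ``(1 + #{permuted F >= observed F}) / (1 + n_permutations)``.

    Samples are internally put in a canonical order (group label, then
    squared-distance row sum) before permutation so that the seeded
    p-value does not depend on input row order.
    """
    d = _check_distance(dist)
    codes, names = _group_codes(groups)
    if len(codes) != len(d):
        raise ValidationError("groups length does not match distance matrix")
    if len(names) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes, minlength=len(names))
    for name, size in zip(names, sizes):
        if size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 samples")
    if n_permutations < 99:
        raise ValidationError("n_permutations must be at least 99")

    d2 = d ** 2
    n = len(d)
    a = len(names)
    order = np.lexsort((d2.sum(axis=1), codes))
    d2 = d2[np.ix_(order, order)]
    codes = codes[order]

    sst = d2.sum() / (2.0 * n)
    ssw = _within_ss(d2, codes, a)
    ssb = sst - ssw
    denom = ssw / (n - a)
    f_obs = np.inf if denom == 0 else (ssb / (a - 1)) / denom

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
    # Within-group SS for all permutations at once, one group at a time.
    ssw_perm = np.zeros(n_permutations)
    for g in range(a):
        z = (perms == g).astype(float)
        ssw_perm += np.einsum("bi,ij,bj->b", z, d2, z) / (2.0 * sizes[g])
    ssb_perm = sst - ssw_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb_perm / (a - 1)) / (ssw_perm / (n - a))
    f_perm = np.where(np.isfinite(f_perm), f_perm, np.inf)
    count = int((f_perm >= f_obs).sum())
    p = (1.0 + count) / (1.0 + n_permutations)
    r2 = 0.0 if sst == 0 else ssb / sst
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r2), p_value=float(p),
                           n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# beta-dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series        # per-sample distance to its group centroid
    group_means: pd.Series      # mean dispersion per group
    u_statistic: float
    p_value: float


def beta_dispersion(dist: pd.DataFrame | np.ndarray, groups) -> DispersionResult:
    """Distance of each sample to its group centroid, plus a group test.

    For Euclidean distances the squared distance of sample i to the
    centroid of its group g satisfies

        d^2(i, c_g) = (1/n_g) sum_{j in g} d_ij^2 - (1/n_g^2) sum_{j<k in g} d_jk^2

    so the centroid never has to be formed explicitly. Group dispersions
    are compared with a two-sided Mann-Whitney U test (two groups).
    """
    d = _check_distance(dist)
    codes, names = _group_codes(groups)
    if len(codes) != len(d):
        raise ValidationError("groups length does not match distance matrix")
    sizes = np.bincount(codes, minlength=len(names))
    for name, size in zip(names, sizes):
        if size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 samples")
    d2 = d ** 2
    dist_to_centroid = np.zeros(len(d))
    for g, n_g in enumerate(sizes):
        members = codes == g
        block = d2[np.ix_(members, members)]
        mean_to_others = d2[:, members].sum(axis=1)[members] / n_g
        correction = block.sum() / (2.0 * n_g ** 2)
        dist_to_centroid[members] = np.sqrt(np.clip(mean_to_others - correction, 0.0, None))
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(len(d))
    distances = pd.Series(dist_to_centroid, index=index, name="distance_to_centroid")
    group_means = pd.Series(
        {name: dist_to_centroid[codes == g].mean() for g, name in enumerate(names)})
    if len(names) != 2:
        raise ValidationError("dispersion group test requires exactly two groups")
    u, p = _mannwhitney(dist_to_centroid[codes == 0], dist_to_centroid[codes == 1])
    return DispersionResult(distances=distances, group_means=group_means,
                            u_statistic=float(u), p_value=float(p))


# ---------------------------------------------------------------------------
# Mann-Whitney + FDR
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    p_adjusted: float
    direction: str


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # fully tied data: no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mannwhitney_fdr(
    data: pd.DataFrame,
    groups: pd.Series,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per metric column, BH-adjusted together.

    ``data`` holds one column per metric and one row per sample;
    ``groups`` assigns each sample to one of exactly two groups. Columns
    form a single FDR family. Rows with NaN in a metric are dropped for
    that metric only. The direction label names the group with the
    larger median (or "none").
    """
    groups = pd.Series(groups).reindex(data.index)
    if groups.isna().any():
        raise ValidationError("every sample needs a group label")
    names = group_order if group_order is not None else tuple(sorted(groups.unique()))
    if len(set(groups)) != 2 or len(names) != 2:
        raise ValidationError("mannwhitney_fdr requires exactly two groups")
    a_mask = (groups == names[0]).to_numpy()
    b_mask = (groups == names[1]).to_numpy()
    rows = []
    for metric in data.columns:
        values = data[metric].to_numpy(float)
        x = values[a_mask & ~np.isnan(values)]
        y = values[b_mask & ~np.isnan(values)]
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(f"metric {metric!r}: fewer than 2 values in a group")
        u, p = _mannwhitney(x, y)
        med_a, med_b = float(np.median(x)), float(np.median(y))
        if med_a > med_b:
            direction = f"{names[0]}>{names[1]}"
        elif med_b > med_a:
            direction = f"{names[1]}>{names[0]}"
        else:
            direction = "none"
        rows.append([metric, names[0], names[1], med_a, med_b, u, p, direction])
    out = pd.DataFrame(rows, columns=[
        "metric", "group_a", "group_b", "median_a", "median_b",
        "u_statistic", "p_value", "direction"])
    out["p_adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out[["metric", "group_a", "group_b", "median_a", "median_b",
                "u_statistic", "p_value", "p_adjusted", "direction"]]
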