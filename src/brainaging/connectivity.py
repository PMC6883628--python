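"""Expression connectivity between brain regions and hemispheres.

Each brain region is summarized by its per-gene mean expression over the
samples of one age group; "connectivity" between two regions is the
Pearson (or Spearman) correlation of those profiles.  Young and aged
connectivity matrices are compared with a two-sided Mann-Whitney U test
(continuity-corrected normal approximation) on their correlation values:
upper triangle for square region x region matrices, the full rectangle
for left x right hemisphere matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from brainaging.normalize import ExpressionMatrix

__all__ = [
    "MWUVerdict",
    "ConnectivityResult",
    "region_profiles",
    "pairwise_correlation",
    "compare_connectivity",
    "hemisphere_symmetry",
    "pairwise_deg_counts",
    "cluster_regions",
]


@dataclass(frozen=True)
class MWUVerdict:
    statistic: float
    p_value: float
    direction: float          # median(young values) - median(aged values)

    @property
    def attenuated_in_aged(self) -> bool:
        return self.direction > 0


@dataclass(frozen=True)
class ConnectivityResult:
    """Connectivity matrices per age group plus their MWU comparison."""

    young: pd.DataFrame
    aged: pd.DataFrame
    method: str
    comparison: MWUVerdict | None = None


def region_profiles(
    expr: ExpressionMatrix,
    group: str,
    scope: str | None = None,
    pool_hemispheres: bool = True,
) -> pd.DataFrame:
    """Per-region mean expression profiles (genes x regions) for one group.

    ``scope`` restricts to one region class (``cortex``/``noncortex``).
    With ``pool_hemispheres=False`` columns are (region, hemisphere)
    pairs labelled ``region|hemisphere``.  Regions without samples in the
    group are omitted with a warning.
    """
    meta = expr.metadata
    if meta is None:
        raise ValueError("expression matrix carries no sample metadata")
    mask = meta["age_group"] == group
    if scope is not None:
        mask &= meta["region_class"] == scope
    sub = meta.loc[mask]
    if sub.empty:
        raise ValueError(f"no samples for group={group!r}, scope={scope!r}")
    keys = sub["region"] if pool_hemispheres else sub["region"] + "|" + sub["hemisphere"]
    profiles = {}
    for key, ids in keys.groupby(keys).groups.items():
        profiles[key] = expr.values[list(ids)].mean(axis=1)
    if pool_hemispheres:
        scope_meta = meta if scope is None else meta[meta["region_class"] == scope]
        lost = set(scope_meta["region"].unique()) - set(profiles)
        if lost:
            warnings.warn(f"regions with no {group} samples omitted: {sorted(lost)}")
    return pd.DataFrame(profiles)


def pairwise_correlation(profiles: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Symmetric region x region correlation matrix with unit diagonal."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 profiles")
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method}")
    return profiles.corr(method=method)


def _mwu(x: np.ndarray, y: np.ndarray) -> MWUVerdict:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    direction = float(np.median(x) - np.median(y))
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values tied: no evidence of any difference
        return MWUVerdict(statistic=len(x) * len(y) / 2.0, p_value=1.0, direction=0.0)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True, method="asymptotic")
    return MWUVerdict(statistic=float(res.statistic), p_value=float(res.pvalue), direction=direction)


def compare_connectivity(young: pd.DataFrame, aged: pd.DataFrame) -> MWUVerdict:
    """Two-sided MWU on the upper-triangle correlations of both groups.

    For square matrices over the same regions the diagonal is excluded;
    matrices must share their region labels.  Direction > 0 means the
    young correlations have the larger median (attenuation in aged).
    """
    if list(young.index) != list(aged.index) or list(young.columns) != list(aged.columns):
        raise ValueError("matrices must cover the same region pairs")
    square = list(young.index) == list(young.columns)
    if square:
        iu = np.triu_indices(young.shape[0], k=1)
        xv, yv = young.to_numpy()[iu], aged.to_numpy()[iu]
    else:
        xv, yv = young.to_numpy().ravel(), aged.to_numpy().ravel()
    if len(xv) < 3:
        raise ValueError("need at least 3 region pairs to compare")
    return _mwu(xv, yv)


def hemisphere_symmetry(
    expr: ExpressionMatrix, group: str, scope: str | None = None, method: str = "pearson"
) -> pd.DataFrame:
    """Right x left hemisphere correlation matrix for one age group.

    Rows are right-hemisphere regions, columns left-hemisphere regions;
    regions sampled on only one side are omitted with a warning.
    """
    prof = region_profiles(expr, group, scope=scope, pool_hemispheres=False)
    left = {c.split("|")[0]: c for c in prof.columns if c.endswith("|L")}
    right = {c.split("|")[0]: c for c in prof.columns if c.endswith("|R")}
    common = sorted(set(left) & set(right))
    lost = (set(left) | set(right)) - set(common)
    if lost:
        warnings.warn(f"regions sampled on one hemisphere only omitted: {sorted(lost)}")
    if len(common) < 2:
        raise ValueError("need both hemispheres sampled for at least 2 regions")
    corr = prof.corr(method=method)
    mat = pd.DataFrame(
        [[corr.loc[right[r], left[l]] for l in common] for r in common],
        index=common,
        columns=common,
    )
    mat.index.name, mat.columns.name = "right", "left"
    return mat


def pairwise_deg_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    scope: str | None = None,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> pd.DataFrame:
    """Number of DEGs between every pair of regions within one age group.

    Runs the negative-binomial Wald test between the two regions' samples
    for each unordered region pair; the returned matrix is symmetric with
    a zero diagonal.
    """
    from brainaging import diffexpr

    meta = metadata
    mask = meta["age_group"] == group
    if scope is not None:
        mask &= meta["region_class"] == scope
    sub = meta.loc[mask]
    regions = sorted(sub["region"].unique())
    mat = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            ids_a = sub.index[sub["region"] == ra]
            ids_b = sub.index[sub["region"] == rb]
            if len(ids_a) < 2 or len(ids_b) < 2:
                continue
            pair = counts[list(ids_a) + list(ids_b)]
            labels = pd.Series(
                ["A"] * len(ids_a) + ["B"] * len(ids_b), index=pair.columns
            )
            res = diffexpr.de_test(pair, labels, reference="A", treatment="B")
            n = len(diffexpr.call_degs(res, p_cut=p_cut, fc_cut=fc_cut))
            mat.loc[ra, rb] = mat.loc[rb, ra] = n
    return mat


def cluster_regions(profiles: pd.DataFrame, method: str = "average"):
    """Agglomerative clustering of region profiles on 1 - Pearson r.

    Returns ``(linkage_matrix, labels)``; labels follow the input column
    order, which also provides the deterministic tie-break.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 profiles to cluster")
    corr = profiles.corr().to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return Z, list(profiles.columns)
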