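"""Weighted co-expression modules and modular differential connectivity.

Modules are detected WGCNA-style on the aged-group expression matrix:
gene-gene adjacency ``|r|^power`` (unsigned, soft-thresholded at a power
chosen by scale-free fit), topological overlap matrix (TOM) similarity,
average-linkage clustering of ``1 - TOM`` with a static tree cut, a
minimum module size, and merging of modules with highly correlated
eigengenes.  Genes falling in clusters below the minimum size stay
"unassigned".

Modular differential connectivity (MDC) is the ratio of the mean
``|r|^power`` connectivity over a module's gene pairs in the aged group
to the same quantity in the young group; gain and loss of connectivity
are judged on ``log2(MDC)`` against a permutation null in which sample
group labels are shuffled, with BH correction over modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from brainaging.diffexpr import bh_fdr, celltype_enrichment, overlap_significance
from brainaging.normalize import ExpressionMatrix, adjust_covariates

__all__ = [
    "ModuleSet",
    "correct_region_covariate",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "compute_mdc",
    "mdc_significance",
    "rank_modules_by_deg",
    "module_celltype_enrichment",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleSet:
    """Gene -> module assignment plus per-module annotations.

    ``membership`` maps every gene to a module label (or ``unassigned``);
    ``power`` is the soft-threshold used for adjacency and MDC.  MDC
    values/verdicts and enrichment tables are attached by the dedicated
    functions and start empty.
    """

    membership: pd.Series
    power: float
    eigengenes: pd.DataFrame | None = None
    mdc: pd.DataFrame | None = None
    annotations: dict = field(default_factory=dict)

    def modules(self, include_unassigned: bool = False) -> list[str]:
        labels = [m for m in self.membership.unique() if m != UNASSIGNED]

        def _key(lbl: str):
            return (-(self.membership == lbl).sum(), lbl)

        labels.sort(key=_key)
        if include_unassigned and (self.membership == UNASSIGNED).any():
            labels.append(UNASSIGNED)
        return labels

    def genes_of(self, module: str) -> pd.Index:
        return self.membership.index[self.membership == module]

    def sizes(self) -> pd.Series:
        return self.membership.value_counts()


def correct_region_covariate(expr: ExpressionMatrix, regions: pd.Series) -> ExpressionMatrix:
    """Regress region indicator effects out of every gene (OLS residual)."""
    cov = pd.DataFrame({"region": regions.reindex(expr.samples)})
    return adjust_covariates(expr, cov)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) vs log10 k over equal-width degree bins."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = ((ys - fitted) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix | pd.DataFrame,
    powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12),
    r2_cut: float = 0.8,
    fallback: int = 6,
    min_mean_degree: float = 1.0,
) -> int:
    """Smallest power whose unsigned network is approximately scale-free.

    The degree distribution of ``|r|^power`` must reach a log-log
    regression R^2 of ``r2_cut`` with negative slope while keeping a mean
    connectivity of at least ``min_mean_degree`` (ruling out powers that
    merely crush the network toward zero degree); when no candidate
    qualifies the documented default is returned with a warning.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 20:
        raise ValueError("need at least 20 genes to pick a soft threshold")
    corr = np.corrcoef(values.to_numpy())
    np.fill_diagonal(corr, 0.0)
    a = np.abs(corr)
    for power in sorted(powers):
        k = (a**power).sum(axis=1)
        if k.mean() < min_mean_degree:
            continue
        r2, slope = _scale_free_fit(k)
        if r2 >= r2_cut and slope < 0:
            return int(power)
    warnings.warn(f"no candidate power reached scale-free R^2 {r2_cut}; using {fallback}")
    return int(fallback)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap from an adjacency with entries in [0, 1].

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L = A @ A`` over shared neighbors and unit diagonal.
    """
    a = np.array(adjacency, float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(values: pd.DataFrame) -> pd.Series:
    """First principal-component score of a module's standardized expression.

    The sign is fixed so the eigengene correlates positively with the
    module's mean expression profile.
    """
    x = values.to_numpy(float)
    sd = x.std(axis=1, keepdims=True)
    xs = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    pc = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    return pd.Series(pc, index=values.columns)


def detect_modules(
    expr: ExpressionMatrix | pd.DataFrame,
    power: int,
    min_size: int = 24,
    cut_height: float = 0.97,
    merge_height: float = 0.25,
    seed: int | None = None,
) -> ModuleSet:
    """Detect co-expression modules by TOM clustering with a static cut.

    ``cut_height`` cuts the average-linkage tree on ``1 - TOM`` distance;
    clusters below ``min_size`` become ``unassigned``; modules whose
    eigengene correlation exceeds ``1 - merge_height`` are merged
    iteratively.  The procedure is deterministic (``seed`` is accepted
    for interface uniformity only) and labels are assigned in decreasing
    module size: ``module_1``, ``module_2``, ...
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = values.index
    if len(genes) < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned")
        return ModuleSet(membership=pd.Series(UNASSIGNED, index=genes), power=power)

    corr = np.corrcoef(values.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** power
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    membership = pd.Series(UNASSIGNED, index=genes, dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    for c in keep:
        membership.iloc[np.where(raw == c)[0]] = f"raw_{c}"

    membership = _merge_similar_modules(membership, values, merge_height)

    # relabel by decreasing size, deterministic tie-break by first gene
    labels = [m for m in membership.unique() if m != UNASSIGNED]
    labels.sort(key=lambda m: (-(membership == m).sum(), membership.index[membership == m][0]))
    rename = {m: f"module_{i + 1}" for i, m in enumerate(labels)}
    membership = membership.map(lambda m: rename.get(m, UNASSIGNED))

    eig = {
        m: module_eigengene(values.loc[membership == m])
        for m in rename.values()
    }
    eigengenes = pd.DataFrame(eig) if eig else None
    return ModuleSet(membership=membership, power=power, eigengenes=eigengenes)


def _merge_similar_modules(
    membership: pd.Series, values: pd.DataFrame, merge_height: float
) -> pd.Series:
    """Merge modules whose eigengenes correlate above 1 - merge_height."""
    membership = membership.copy()
    while True:
        labels = [m for m in membership.unique() if m != UNASSIGNED]
        if len(labels) < 2:
            return membership
        eig = pd.DataFrame({m: module_eigengene(values.loc[membership == m]) for m in labels})
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= 1.0 - merge_height:
            return membership
        keep, absorb = sorted((labels[i], labels[j]))
        membership[membership == absorb] = keep


def _pair_connectivity(values: np.ndarray, power: float) -> float:
    """Mean |r|^power over off-diagonal gene pairs of a module submatrix."""
    corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float((np.abs(corr[iu]) ** power).mean())


def compute_mdc(
    moduleset: ModuleSet,
    expr_young: ExpressionMatrix | pd.DataFrame,
    expr_aged: ExpressionMatrix | pd.DataFrame,
) -> pd.DataFrame:
    """MDC per module: mean aged pair connectivity / mean young.

    Connectivity of a gene pair is ``|r|^power`` within each group at the
    module set's power.  Modules need >= 2 genes present in both
    matrices.  Returns a frame with ``mdc`` and ``log2_mdc``.
    """
    vy = expr_young.values if isinstance(expr_young, ExpressionMatrix) else expr_young
    va = expr_aged.values if isinstance(expr_aged, ExpressionMatrix) else expr_aged
    rows = {}
    for m in moduleset.modules():
        genes = moduleset.genes_of(m)
        if genes.difference(vy.index).size or genes.difference(va.index).size:
            raise ValueError(f"module {m} genes missing from an expression matrix")
        if len(genes) < 2:
            continue
        cy = _pair_connectivity(vy.loc[genes].to_numpy(), moduleset.power)
        ca = _pair_connectivity(va.loc[genes].to_numpy(), moduleset.power)
        mdc = ca / cy if cy > 0 else np.inf
        rows[m] = {"mdc": mdc, "log2_mdc": float(np.log2(mdc)) if mdc > 0 else -np.inf}
    table = pd.DataFrame(rows).T
    moduleset.mdc = table
    return table


def mdc_significance(
    moduleset: ModuleSet,
    expr_young: ExpressionMatrix | pd.DataFrame,
    expr_aged: ExpressionMatrix | pd.DataFrame,
    n_perm: int = 1000,
    q_cut: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation verdicts for MDC: gain / loss / none per module.

    The null shuffles the young/aged sample labels, preserving group
    sizes, and recomputes ``log2(MDC)``; the two-sided p-value is the
    fraction of null values at least as extreme as observed (with the
    +1 correction).  BH across modules; gain when ``log2(MDC) > 0`` and
    ``q < q_cut``, loss when negative and significant, else none.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    vy = expr_young.values if isinstance(expr_young, ExpressionMatrix) else expr_young
    va = expr_aged.values if isinstance(expr_aged, ExpressionMatrix) else expr_aged
    observed = compute_mdc(moduleset, vy, va)
    modules = list(observed.index)
    combined = pd.concat([vy, va], axis=1)
    n_young = vy.shape[1]
    rng = np.random.default_rng(seed)

    null = np.empty((n_perm, len(modules)))
    gene_blocks = {m: combined.loc[moduleset.genes_of(m)].to_numpy() for m in modules}
    for b in range(n_perm):
        perm = rng.permutation(combined.shape[1])
        yc, ac = perm[:n_young], perm[n_young:]
        for j, m in enumerate(modules):
            block = gene_blocks[m]
            cy = _pair_connectivity(block[:, yc], moduleset.power)
            ca = _pair_connectivity(block[:, ac], moduleset.power)
            null[b, j] = np.log2(ca / cy) if cy > 0 and ca > 0 else 0.0

    obs = observed["log2_mdc"].to_numpy()
    p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)) / (n_perm + 1.0)
    q = bh_fdr(pd.Series(p, index=modules)).to_numpy()
    verdict = np.where(
        (q < q_cut) & (obs > 0), "gain", np.where((q < q_cut) & (obs < 0), "loss", "none")
    )
    table = observed.assign(p=p, q=q, verdict=verdict)
    moduleset.mdc = table
    return table


def rank_modules_by_deg(
    moduleset: ModuleSet,
    deg_sets: dict[str, set],
    universe,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Rank modules by DEG enrichment across regions ("importance").

    Fisher enrichment of each module's genes in each region's DEG set,
    BH-corrected over all module x region tests.  Importance is the
    number of regions significant at ``q < q_cut``; ties are broken by
    mean ``-log10 q``.  Rank 1 is the most DEG-enriched module.
    """
    modules = moduleset.modules()
    rows = []
    for m in modules:
        genes = set(moduleset.genes_of(m))
        for region, degs in deg_sets.items():
            odds, p = overlap_significance(genes, set(degs) & set(universe), universe)
            rows.append({"module": m, "region": region, "odds_ratio": odds, "p": p})
    flat = pd.DataFrame(rows)
    flat["q"] = bh_fdr(flat["p"]).to_numpy()
    agg = []
    for m in modules:
        sub = flat[flat["module"] == m]
        importance = int((sub["q"] < q_cut).sum())
        mean_score = float(-np.log10(np.maximum(sub["q"], 1e-300)).mean())
        agg.append({"module": m, "importance": importance, "mean_neglog10_q": mean_score})
    table = pd.DataFrame(agg).set_index("module")
    table = table.sort_values(["importance", "mean_neglog10_q"], ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    moduleset.annotations["deg_enrichment"] = flat
    return table


def module_celltype_enrichment(
    moduleset: ModuleSet, celltype_sets: dict[str, set], universe
) -> pd.DataFrame:
    """Cell-type Fisher enrichment per module (BH within each module)."""
    tables = []
    for m in moduleset.modules():
        t = celltype_enrichment(set(moduleset.genes_of(m)), celltype_sets, universe)
        t.insert(0, "module", m)
        tables.append(t)
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    moduleset.annotations["celltype_enrichment"] = out
    return out
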