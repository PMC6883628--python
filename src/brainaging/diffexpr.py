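"""Two-group differential expression on counts, plus overlap and
cell-type enrichment statistics.

The DE engine is a negative-binomial Wald test: median-of-ratios size
factors, gene-wise dispersion by method of moments (floored at 1e-8), a
log-link two-group model, and a two-sided Wald test on the group
coefficient referenced to a t distribution with ``n - 2`` degrees of
freedom (the small-sample analogue of the normal reference; with the
group sizes typical here the two are close, and the t reference keeps
the null test size at its nominal level).  DEGs are genes with
``p < 0.05`` and linear fold change above 1.5 in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "size_factors",
    "de_test",
    "call_degs",
    "bh_fdr",
    "overlap_rate",
    "overlap_significance",
    "build_celltype_sets",
    "celltype_enrichment",
    "CELL_TYPES",
]

CELL_TYPES = ("neuron", "microglia", "astrocyte", "oligodendrocyte", "endothelial")

_DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class DEResult:
    """Per-gene DE statistics: log2fc (treatment vs reference), p, BH q."""

    table: pd.DataFrame
    reference: str
    treatment: str

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Only genes with non-zero counts in every sample contribute to the
    reference; if none exist, library-size ratios are used instead.
    """
    x = counts.to_numpy(float)
    positive = (x > 0).all(axis=1)
    if positive.sum() >= 1:
        logx = np.log(x[positive])
        ref = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - ref, axis=0))
    else:
        lib = x.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    sf = sf / np.exp(np.mean(np.log(sf)))     # geometric mean 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moment_dispersion(norm: np.ndarray, groups: np.ndarray, inv_sf: np.ndarray) -> np.ndarray:
    """Gene-wise NB dispersion from within-group moments of normalized counts.

    Var(k/s) = mu/s + alpha*mu^2, so alpha = (within-group variance -
    mu * mean(1/s)) / mu^2, pooled over the two groups and floored.
    """
    n = norm.shape[1]
    resid = np.empty_like(norm)
    mu = np.empty_like(norm)
    for g in np.unique(groups):
        cols = groups == g
        m = norm[:, cols].mean(axis=1, keepdims=True)
        resid[:, cols] = norm[:, cols] - m
        mu[:, cols] = m
    df = max(n - 2, 1)
    var_within = (resid**2).sum(axis=1) / df
    mean_overall = norm.mean(axis=1)
    poisson_part = mean_overall * inv_sf.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - poisson_part) / np.maximum(mean_overall, 1e-12) ** 2
    return np.clip(np.nan_to_num(alpha, nan=_DISPERSION_FLOOR), _DISPERSION_FLOOR, None)


def de_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    reference: str = "young",
    treatment: str = "aged",
) -> DEResult:
    """NB Wald test of ``treatment`` vs ``reference`` for every gene.

    Genes with zero counts throughout one of the groups cannot support a
    finite log fold change estimate; they are reported with ``p = 1`` and
    ``log2fc = 0`` (and flagged in the ``degenerate`` column).
    """
    groups = groups.reindex(counts.columns)
    for g in (reference, treatment):
        if (groups == g).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {g!r}")
    cols = groups.isin([reference, treatment])
    counts = counts.loc[:, cols]
    groups = groups[cols]

    sf = size_factors(counts).to_numpy()
    inv_sf = 1.0 / sf
    x = counts.to_numpy(float)
    norm = x * inv_sf[None, :]
    glab = (groups == treatment).to_numpy().astype(int)
    n0 = int((glab == 0).sum())
    n1 = int((glab == 1).sum())

    alpha = _moment_dispersion(norm, glab, inv_sf)
    m0 = norm[:, glab == 0].mean(axis=1)
    m1 = norm[:, glab == 1].mean(axis=1)
    degenerate = (m0 == 0) | (m1 == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(m1) - np.log(m0)                     # natural log FC
        # Var(mean_g of k/s) = (mu * sum(1/s_j) / n_g^2) + alpha * mu^2 / n_g
        s0 = inv_sf[glab == 0].sum()
        s1 = inv_sf[glab == 1].sum()
        var0 = s0 / (n0**2 * np.maximum(m0, 1e-300)) + alpha / n0
        var1 = s1 / (n1**2 * np.maximum(m1, 1e-300)) + alpha / n1
        se = np.sqrt(var0 + var1)
        z = beta / se
    df = n0 + n1 - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)
    log2fc = beta / np.log(2.0)

    log2fc = np.where(degenerate, 0.0, log2fc)
    p = np.where(degenerate, 1.0, p)
    q = bh_fdr(pd.Series(p, index=counts.index)).to_numpy()

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "degenerate": degenerate,
        },
        index=counts.index,
    )
    return DEResult(table=table, reference=reference, treatment=treatment)


def call_degs(res: DEResult, p_cut: float = 0.05, fc_cut: float = 1.5) -> pd.Index:
    """Genes with p below ``p_cut`` and linear |FC| above ``fc_cut``.

    Both thresholds are strict (p < p_cut, |log2fc| > log2(fc_cut)),
    matching the convention of calling at "p < 0.05 and FC > 1.5".
    """
    t = res.table
    flag = (t["p"] < p_cut) & (t["log2fc"].abs() > np.log2(fc_cut))
    return t.index[flag]


def bh_fdr(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    return pd.Series(q, index=pvalues.index, name="q")


def overlap_rate(set_a, set_b) -> float:
    """Jaccard overlap |A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_significance(set_a, set_b, universe) -> tuple[float, float]:
    """One-sided Fisher's exact test for over-representation.

    Returns ``(odds_ratio, p)`` for the 2x2 table of universe membership
    in A and B.  Sets must be subsets of the universe.
    """
    uni = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uni or not b <= uni:
        raise ValueError("sets must be contained in the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(uni) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return float(odds), float(p)


def build_celltype_sets(reference: pd.DataFrame, fold: float = 5.0) -> dict[str, set]:
    """Assign genes to the cell type where they are >= ``fold`` x all others.

    ``reference`` is a gene x cell-type non-negative expression matrix
    whose columns are the five brain cell types.  The fold boundary is
    inclusive; genes clearing it for no cell type stay unassigned.  The
    resulting sets are disjoint by construction.
    """
    if (reference < 0).any().any():
        raise ValueError("reference expression must be non-negative")
    x = reference.to_numpy(float)
    sets: dict[str, set] = {ct: set() for ct in reference.columns}
    order = np.argsort(x, axis=1)
    top = order[:, -1]
    second = x[np.arange(len(x)), order[:, -2]]
    ok = x[np.arange(len(x)), top] >= fold * second
    # a gene with all-zero expression is unassigned (0 >= 0 is vacuous evidence)
    ok &= x[np.arange(len(x)), top] > 0
    for i in np.where(ok)[0]:
        sets[reference.columns[top[i]]].add(reference.index[i])
    return sets


def celltype_enrichment(
    de_genes: dict[str, set] | pd.Index,
    celltype_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Fisher enrichment of DE genes in each cell-type set, BH-corrected.

    ``de_genes`` may be a mapping direction -> gene set (e.g. "up"/"down",
    giving 5 x directions tests corrected together) or a single gene
    collection.
    """
    if not isinstance(de_genes, dict):
        de_genes = {"all": set(de_genes)}
    rows = []
    for direction, genes in de_genes.items():
        for ct, ct_set in celltype_sets.items():
            odds, p = overlap_significance(set(genes), ct_set, universe)
            rows.append({"direction": direction, "cell_type": ct, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"]).to_numpy() if len(table) else []
    return table
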