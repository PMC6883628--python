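"""Differential exon usage (DEU) between age groups.

Exon usage is an exon's share of its gene's reads.  The default test
pools counts within each group and, for every exon, forms the 2x2 table
(exon count vs rest-of-gene count, young vs aged) tested by chi-squared
with continuity correction, falling back to Fisher's exact test whenever
an expected cell is below 5.  p-values are BH-corrected across exons and
a gene is flagged as a DEU gene when any of its exons is significant at
``p < 0.01``.

Pooling across samples ignores between-sample overdispersion; an
overdispersion-robust alternative — a two-sample t-test on per-sample
logit usage — is available via ``method="logit_t"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from brainaging.diffexpr import bh_fdr

__all__ = ["DEUResult", "exon_usage_test", "call_deus", "deg_deu_relation", "usage_fractions"]


@dataclass(frozen=True)
class DEUResult:
    """Per-exon usage statistics; ``table`` is indexed by (gene, exon)."""

    table: pd.DataFrame
    p_cut: float = 0.01

    def gene_flags(self, p_cut: float | None = None) -> pd.Series:
        cut = self.p_cut if p_cut is None else p_cut
        return self.table.groupby(level="gene_id")["p"].min() < cut


def usage_fractions(exon_counts: pd.DataFrame) -> pd.DataFrame:
    """Exon share of gene total, per sample; sums to 1 within each gene.

    Invariant to rescaling any sample's counts by a constant.  Samples
    where a gene has zero total are NaN.
    """
    totals = exon_counts.groupby(level="gene_id").transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        return exon_counts / totals


def _pooled_table_test(a: int, b: int, c: int, d: int) -> float:
    """p for 2x2 [exon, rest] x [young, aged]; chi2 w/ Yates, Fisher if sparse."""
    table = np.array([[a, b], [c, d]], float)
    if table.sum() == 0:
        return 1.0
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def exon_usage_test(
    exon_counts: pd.DataFrame,
    groups: pd.Series,
    reference: str = "young",
    treatment: str = "aged",
    method: str = "pooled",
    p_cut: float = 0.01,
) -> DEUResult:
    """Test every exon for differential usage between the two groups.

    ``exon_counts`` is indexed by (gene_id, exon_id).  Genes with a single
    exon carry no usage information and are skipped with a warning; genes
    with zero totals in either group are skipped likewise.
    """
    import warnings

    if method not in ("pooled", "logit_t"):
        raise ValueError(f"unknown DEU method: {method}")
    groups = groups.reindex(exon_counts.columns)
    ref_cols = groups == reference
    trt_cols = groups == treatment
    if ref_cols.sum() < 1 or trt_cols.sum() < 1:
        raise ValueError("both groups must be present among samples")

    rows = []
    skipped = []
    for gene, sub in exon_counts.groupby(level="gene_id", sort=False):
        if len(sub) < 2:
            skipped.append(gene)
            continue
        ref_tot = sub.loc[:, ref_cols.to_numpy()].to_numpy()
        trt_tot = sub.loc[:, trt_cols.to_numpy()].to_numpy()
        if ref_tot.sum() == 0 or trt_tot.sum() == 0:
            skipped.append(gene)
            continue
        ref_sum = ref_tot.sum(axis=1)
        trt_sum = trt_tot.sum(axis=1)
        for e in range(len(sub)):
            exon_id = sub.index[e][1]
            a, c = int(ref_sum[e]), int(trt_sum[e])
            b, d = int(ref_sum.sum() - a), int(trt_sum.sum() - c)
            u_ref = a / max(ref_sum.sum(), 1)
            u_trt = c / max(trt_sum.sum(), 1)
            if method == "pooled":
                p = _pooled_table_test(a, b, c, d)
            else:
                p = _logit_usage_t(ref_tot[e], ref_tot.sum(axis=0), trt_tot[e], trt_tot.sum(axis=0))
            rows.append(
                {
                    "gene_id": gene,
                    "exon_id": exon_id,
                    "usage_ref": u_ref,
                    "usage_trt": u_trt,
                    "p": p,
                }
            )
    if skipped:
        warnings.warn(f"skipped {len(skipped)} gene(s) with one exon or empty group totals")
    table = pd.DataFrame(rows)
    if table.empty:
        idx = pd.MultiIndex.from_tuples([], names=["gene_id", "exon_id"])
        table = pd.DataFrame(
            {c: [] for c in ["usage_ref", "usage_trt", "p", "q"]}, index=idx
        )
        return DEUResult(table=table, p_cut=p_cut)
    table = table.set_index(["gene_id", "exon_id"])
    table["q"] = bh_fdr(table["p"]).to_numpy()
    return DEUResult(table=table, p_cut=p_cut)


def _logit_usage_t(
    exon_ref: np.ndarray, gene_ref: np.ndarray, exon_trt: np.ndarray, gene_trt: np.ndarray
) -> float:
    """Welch t-test on per-sample logit usage (0.5 pseudo-count)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u_ref = (exon_ref + 0.5) / (gene_ref + 1.0)
        u_trt = (exon_trt + 0.5) / (gene_trt + 1.0)
    lo_ref = np.log(u_ref / (1 - u_ref))
    lo_trt = np.log(u_trt / (1 - u_trt))
    lo_ref = lo_ref[np.isfinite(lo_ref)]
    lo_trt = lo_trt[np.isfinite(lo_trt)]
    if len(lo_ref) < 2 or len(lo_trt) < 2:
        return 1.0
    if np.ptp(np.concatenate([lo_ref, lo_trt])) == 0:
        return 1.0
    return float(stats.ttest_ind(lo_ref, lo_trt, equal_var=False).pvalue)


def call_deus(res: DEUResult, p_cut: float = 0.01) -> pd.Index:
    """Genes with at least one exon below ``p_cut`` (any-exon rule)."""
    flags = res.gene_flags(p_cut)
    return flags.index[flags]


def deg_deu_relation(
    deg_counts: pd.Series, deu_counts: pd.Series
) -> dict[str, float]:
    """Pearson relation between per-region DEG and DEU-gene counts.

    Returns ``r``, ``r2`` and the two-sided ``p`` across regions (the
    series must share their region index; >= 3 regions required).
    """
    regions = deg_counts.index.intersection(deu_counts.index)
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    x = deg_counts.loc[regions].to_numpy(float)
    y = deu_counts.loc[regions].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": 0.0, "r2": 0.0, "p": 1.0}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r2": float(r**2), "p": float(p)}
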