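"""Sample- and gene-level quality control.

Samples are screened in two steps: an RNA-integrity (RIN) cutoff, and an
outlier rule on seven sequencing-quality metrics.  Each metric is
standardized to a z-score across the samples under evaluation; a value
counts as an outlier when it lies more than ``z_cut`` standard deviations
in that metric's *bad* direction (high for %Intergenic Bases, GC Dropout
and AT Dropout; low for %Total Reads, %High-quality Aligned Reads, %mRNA
Bases and Median 5'->3' Bias).  A sample with more than one outlier
metric is removed.

Genes are screened per stratum (cortex / non-cortex samples separately):
a gene is detected in a stratum when it reaches ``min_count`` counts in
at least ``min_fraction`` of that stratum's samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from brainaging.synthdata import METRICS_BAD_HIGH, METRICS_BAD_LOW, QUALITY_METRICS

__all__ = [
    "QCVerdicts",
    "GeneFilterResult",
    "compute_quality_zscores",
    "filter_by_rin",
    "flag_outlier_samples",
    "qc_samples",
    "filter_low_expression_genes",
]


@dataclass(frozen=True)
class QCVerdicts:
    """Per-sample QC outcome.

    ``table`` is indexed by sample id with columns ``rin_pass`` (bool),
    ``outlier_metric_count`` (int), ``retained`` (bool) and ``reasons``
    (semicolon-joined strings).  A sample is retained iff its RIN passes
    and it has at most one outlier metric.
    """

    table: pd.DataFrame

    @property
    def retained(self) -> pd.Index:
        return self.table.index[self.table["retained"]]

    @property
    def removed(self) -> pd.Index:
        return self.table.index[~self.table["retained"]]


def filter_by_rin(quality: pd.DataFrame, cutoff: float = 5.0) -> pd.Series:
    """Boolean pass flag per sample; RIN at or below ``cutoff`` fails.

    The boundary is exclusionary: a sample at exactly the cutoff is
    removed.
    """
    if "rin" not in quality.columns:
        raise ValueError("quality table lacks a 'rin' column")
    rin = quality["rin"]
    if rin.isna().any():
        missing = rin.index[rin.isna()].tolist()
        raise ValueError(f"missing RIN for sample(s): {missing}")
    return rin > cutoff


def compute_quality_zscores(
    quality: pd.DataFrame, metrics: tuple[str, ...] = QUALITY_METRICS
) -> pd.DataFrame:
    """Standardize each metric to mean 0, sd 1 over the given samples.

    A metric that is constant (sd = 0) maps to z = 0 everywhere, so a
    degenerate metric can never create outliers.
    """
    if len(quality) < 3:
        raise ValueError("need at least 3 samples to standardize quality metrics")
    x = quality[list(metrics)]
    if not all(np.issubdtype(dt, np.number) for dt in x.dtypes):
        raise ValueError("non-numeric quality metric column")
    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd.replace(0.0, np.nan)
    return z.fillna(0.0)


def flag_outlier_samples(zscores: pd.DataFrame, z_cut: float = 2.0) -> pd.DataFrame:
    """Count signed outlier metrics per sample and apply the <=1 rule.

    Returns a frame with ``outlier_metric_count``, ``retained`` and
    ``reasons``.  The direction table is authoritative: a z-score beyond
    the cut in the metric's *good* direction is never an outlier, and a
    metric name outside the table is an error.
    """
    unknown = set(zscores.columns) - set(QUALITY_METRICS)
    if unknown:
        raise ValueError(f"unknown quality metric(s): {sorted(unknown)}")
    flags = pd.DataFrame(False, index=zscores.index, columns=zscores.columns)
    for metric in zscores.columns:
        if metric in METRICS_BAD_HIGH:
            flags[metric] = zscores[metric] > z_cut
        else:
            flags[metric] = zscores[metric] < -z_cut
    count = flags.sum(axis=1)
    reasons = flags.apply(lambda row: ";".join(c for c in flags.columns if row[c]), axis=1)
    return pd.DataFrame(
        {
            "outlier_metric_count": count,
            "retained": count <= 1,
            "reasons": reasons,
        }
    )


def qc_samples(
    quality: pd.DataFrame,
    rin_cutoff: float = 5.0,
    z_cut: float = 2.0,
    zscores_after_rin: bool = True,
) -> QCVerdicts:
    """Full sample QC: RIN cutoff then metric-outlier rule.

    By default z-scores are computed over the post-RIN sample set (the
    samples actually under evaluation for sequencing quality); set
    ``zscores_after_rin=False`` to standardize over all samples instead.
    """
    rin_pass = filter_by_rin(quality, rin_cutoff)
    zpool = quality.loc[rin_pass] if zscores_after_rin else quality
    z = compute_quality_zscores(zpool)
    z = z.reindex(quality.index).fillna(0.0)  # RIN-failed samples: metric rule moot
    outliers = flag_outlier_samples(z, z_cut)

    reasons = []
    for s in quality.index:
        r = []
        if not rin_pass.loc[s]:
            r.append(f"RIN<= {rin_cutoff}")
        if rin_pass.loc[s] and not outliers.loc[s, "retained"]:
            r.append(f"quality outliers: {outliers.loc[s, 'reasons']}")
        reasons.append(";".join(r))

    table = pd.DataFrame(
        {
            "rin_pass": rin_pass,
            "outlier_metric_count": outliers["outlier_metric_count"],
            "retained": rin_pass & outliers["retained"],
            "reasons": reasons,
        },
        index=quality.index,
    )
    return QCVerdicts(table=table)


@dataclass(frozen=True)
class GeneFilterResult:
    """Low-expression filtering outcome.

    ``retained_by_stratum`` maps each stratum name to the genes detected
    there; ``detected`` is their union (a gene counts as detected when it
    passes in at least one stratum); ``counts`` is the input restricted
    to detected genes.
    """

    counts: pd.DataFrame
    retained_by_stratum: dict[str, pd.Index]

    @property
    def detected(self) -> pd.Index:
        return self.counts.index


def filter_low_expression_genes(
    counts: pd.DataFrame,
    strata: pd.Series | None = None,
    min_count: int = 10,
    min_fraction: float = 0.8,
) -> GeneFilterResult:
    """Keep genes reaching ``min_count`` in >= ``min_fraction`` of a stratum.

    ``strata`` assigns each sample (column) to a stratum, typically the
    cortex / non-cortex class; ``None`` treats all samples as one
    stratum.  The fraction boundary is inclusive: a gene at exactly 80%
    of samples is retained.
    """
    if strata is None:
        strata = pd.Series("all", index=counts.columns)
    strata = strata.reindex(counts.columns)
    retained: dict[str, pd.Index] = {}
    for name, cols in strata.groupby(strata, observed=False).groups.items():
        if len(cols) == 0:
            raise ValueError(f"empty stratum: {name}")
        sub = counts[list(cols)]
        frac = (sub >= min_count).mean(axis=1)
        retained[str(name)] = counts.index[frac >= min_fraction]
    keep = counts.index[:0]
    for idx in retained.values():
        keep = keep.union(idx)
    keep = counts.index[counts.index.isin(keep)]  # preserve original order
    return GeneFilterResult(counts=counts.loc[keep], retained_by_stratum=retained)
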