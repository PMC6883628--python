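"""GC/depth normalization and covariate removal.

Counts are put on a log2 counts-per-million scale, a smooth per-sample
regression removes the sample-specific dependence of expression on gene
GC fraction and log length, and a per-gene ordinary-least-squares fit
subtracts known technical covariates (batch, sex and the first two
principal components of the sequencing-quality metrics, seqSV1/seqSV2):

    adjusted = original - batch*beta_batch - sex*beta_sex
                        - seqSV1*beta_seqSV1 - seqSV2*beta_seqSV2

Biological terms — age group and brain region — are never part of the
removal design here; region is regressed out only immediately before
module construction (see :mod:`brainaging.coexpression`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brainaging.synthdata import QUALITY_METRICS

__all__ = [
    "ExpressionMatrix",
    "SeqSurrogates",
    "log_cpm",
    "gc_depth_normalize",
    "compute_seq_surrogates",
    "adjust_covariates",
]


@dataclass
class ExpressionMatrix:
    """Continuous gene x sample expression with a transform provenance log."""

    values: pd.DataFrame
    transforms: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, step: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values, transforms=[*self.transforms, step], metadata=self.metadata
        )


@dataclass(frozen=True)
class SeqSurrogates:
    """First two PCs of the (unstandardized) sequencing-quality metrics."""

    table: pd.DataFrame              # columns seqSV1, seqSV2, indexed by sample
    variance_explained: tuple[float, float]


def log_cpm(counts: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + prior); exactly invariant to depth scaling."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    return np.log2(counts.div(libsize, axis=1) * 1.0e6 + prior)


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    xs = (x - x.mean()) / (x.std() or 1.0)
    return np.column_stack([xs**d for d in range(1, degree + 1)])


def gc_depth_normalize(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    degree: int = 3,
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Remove sample-specific GC and length bias from log2 CPM expression.

    For every sample, the deviation of its expression from the per-gene
    mean is regressed on a low-order polynomial in GC fraction plus log
    length, and the fitted smooth is subtracted.  Gene means are
    untouched, so mean expression per gene is preserved up to a constant;
    only the between-sample systematic trends are removed.

    ``annotation`` must carry ``gc_fraction`` in [0, 1] and ``length`` > 0
    for every gene in ``counts``.
    """
    missing = counts.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"genes missing annotation: {list(missing[:10])}")
    ann = annotation.loc[counts.index]
    gc = ann["gc_fraction"].to_numpy(float)
    length = ann["length"].to_numpy(float)
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc_fraction outside [0, 1]")
    if (length <= 0).any():
        raise ValueError("non-positive gene length")

    expr = log_cpm(counts)
    e = expr.to_numpy()
    dev = e - e.mean(axis=1, keepdims=True)

    X = np.column_stack([_poly_design(gc, degree), _poly_design(np.log(length), 1)])
    X = np.column_stack([np.ones(len(gc)), X])
    # One least-squares solve for all samples at once (columns of dev).
    beta, *_ = np.linalg.lstsq(X, dev, rcond=None)
    fitted = X @ beta
    adj = pd.DataFrame(e - fitted, index=expr.index, columns=expr.columns)
    return ExpressionMatrix(
        values=adj, transforms=["log_cpm", f"gc_length_poly{degree}"], metadata=metadata
    )


def compute_seq_surrogates(
    quality: pd.DataFrame, metrics: tuple[str, ...] = QUALITY_METRICS
) -> SeqSurrogates:
    """PCA (centered, unscaled) of the quality metrics; first two PCs.

    Deterministic up to sign, which is fixed by requiring the
    largest-magnitude loading of each component to be positive.
    """
    if len(quality) < 3:
        raise ValueError("need at least 3 samples")
    avail = [m for m in metrics if m in quality.columns]
    if len(avail) < 2:
        raise ValueError("need at least 2 quality metrics")
    x = quality[avail].to_numpy(float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    var = s**2 / max(len(x) - 1, 1)
    total = var.sum()
    out = {}
    ve = []
    for k in range(2):
        load = vt[k]
        sign = np.sign(load[np.argmax(np.abs(load))]) or 1.0
        out[f"seqSV{k + 1}"] = sign * scores[:, k]
        ve.append(float(var[k] / total) if total > 0 else 0.0)
    table = pd.DataFrame(out, index=quality.index)
    return SeqSurrogates(table=table, variance_explained=(ve[0], ve[1]))


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Categorical columns become drop-first indicator columns."""
    blocks = []
    for col in covariates.columns:
        s = covariates[col]
        if np.issubdtype(s.dtype, np.number):
            blocks.append(s.astype(float).to_frame())
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies)
    return pd.concat(blocks, axis=1)


def adjust_covariates(
    expr: ExpressionMatrix, covariates: pd.DataFrame
) -> ExpressionMatrix:
    """Subtract fitted covariate effects, gene by gene, via OLS.

    Covariates are encoded numerically, an intercept is always included
    in the fit but never subtracted, and the adjusted value is
    ``original - X_cov @ beta_cov``.  After adjustment every covariate's
    per-gene regression slope is zero to numerical precision.
    """
    cov = covariates.reindex(expr.samples)
    if cov.isna().any().any():
        raise ValueError("missing covariate values for some samples")
    X = _encode_covariates(cov)
    Xc = X.to_numpy(float)
    design = np.column_stack([np.ones(len(Xc)), Xc])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(f"collinear covariate design among columns: {list(X.columns)}")
    Y = expr.values.to_numpy().T                   # samples x genes
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    removed = Xc @ beta[1:, :]                     # exclude intercept
    adj = pd.DataFrame(
        (Y - removed).T, index=expr.genes, columns=expr.samples
    )
    return expr.with_values(adj, f"adjust[{','.join(map(str, X.columns))}]")
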