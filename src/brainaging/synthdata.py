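"""Synthetic multi-region brain RNA-seq data with planted, recorded effects.

The generator emulates a study design of a few young and a few aged
individuals sampled across tens of brain regions in both hemispheres
(roughly 600 libraries), and draws a gene-level count matrix from a
negative-binomial model whose log-mean combines:

* a gene baseline abundance,
* an age effect for planted differentially expressed genes (DEGs),
* a per-module latent factor shared by module genes, whose coupling
  strength may differ between age groups (planting connectivity gain),
* batch, sex and sequencing-quality covariate effects,
* a sample-specific GC-content bias and a log-normal library size.

Exon-level counts partition each gene's count by a multinomial usage
vector that differs between groups only for planted differential-exon-
usage (DEU) genes.  Every planted effect is recorded in a
:class:`GroundTruth` object so downstream modules can be scored on
recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QUALITY_METRICS",
    "StudyDesign",
    "ModuleSpec",
    "RegionEffect",
    "TruthParams",
    "GroundTruth",
    "make_design",
    "default_regions",
    "simulate_counts",
    "simulate_exon_counts",
    "write_counts_tsv",
    "write_counts_mtx",
]

#: The seven per-sample sequencing-quality metrics tracked by the QC stage.
QUALITY_METRICS = (
    "pct_total_reads",
    "pct_hq_aligned_reads",
    "pct_mrna_bases",
    "pct_intergenic_bases",
    "median_5to3_bias",
    "gc_dropout",
    "at_dropout",
)

# Typical (mean, sd) for each metric on a well-behaved library.
_METRIC_SCALE = {
    "pct_total_reads": (92.0, 2.0),
    "pct_hq_aligned_reads": (88.0, 2.5),
    "pct_mrna_bases": (55.0, 5.0),
    "pct_intergenic_bases": (6.0, 1.5),
    "median_5to3_bias": (0.9, 0.05),
    "gc_dropout": (2.0, 0.8),
    "at_dropout": (1.0, 0.5),
}

# Metrics where a *high* value signals a bad library; the rest are bad low.
METRICS_BAD_HIGH = frozenset({"pct_intergenic_bases", "gc_dropout", "at_dropout"})
METRICS_BAD_LOW = frozenset(QUALITY_METRICS) - METRICS_BAD_HIGH


@dataclass(frozen=True)
class StudyDesign:
    """Sample layout of a multi-region two-age-group study.

    ``samples`` is indexed by sample id and carries one row per sequenced
    library with columns: ``individual``, ``age_group`` (``young`` /
    ``aged``), ``sex``, ``region``, ``region_class`` (``cortex`` /
    ``noncortex``), ``hemisphere`` (``L`` / ``R``), ``batch``, ``rin``,
    ``quality_factor`` (latent sample-quality score driving the metric
    block) and the seven quality metrics.
    """

    samples: pd.DataFrame
    regions: dict[str, str]

    def __post_init__(self) -> None:
        trip = self.samples[["individual", "region", "hemisphere"]]
        if trip.duplicated().any():
            raise ValueError("duplicate (individual, region, hemisphere) triple")
        cls = self.samples.groupby("region")["region_class"].nunique()
        if (cls > 1).any():
            bad = cls[cls > 1].index.tolist()
            raise ValueError(f"region class not constant within region(s): {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def default_regions(n_cortex: int = 28, n_noncortex: int = 16) -> dict[str, str]:
    """Region label -> cortex/non-cortex class for a default 44-region atlas."""
    regions = {f"CTX{i:02d}": "cortex" for i in range(1, n_cortex + 1)}
    regions.update({f"SUB{i:02d}": "noncortex" for i in range(1, n_noncortex + 1)})
    return regions


def make_design(
    n_young: int = 4,
    n_aged: int = 3,
    regions: dict[str, str] | None = None,
    hemispheres: tuple[str, ...] = ("L", "R"),
    dropouts: list[tuple[str, str, str]] | None = None,
    n_batches: int = 2,
    low_quality_fraction: float = 0.0,
    seed: int = 0,
) -> StudyDesign:
    """Lay out samples for ``n_young`` + ``n_aged`` individuals.

    Every individual contributes one library per (region, hemisphere)
    except the ``dropouts`` — explicit (individual, region, hemisphere)
    triples removed from the design, mimicking tissue unavailability.

    ``low_quality_fraction`` of the remaining samples are given either a
    degraded RIN (uniform on [2, 5], at or below the usual exclusion
    cutoff) or two or more quality metrics pushed 3-5 standard deviations
    in their bad direction, so the QC stage has real work to do.
    """
    if n_young < 1 or n_aged < 1:
        raise ValueError("need at least one individual per age group")
    if regions is None:
        regions = default_regions()
    classes = set(regions.values())
    if len(regions) < 2 or classes - {"cortex", "noncortex"}:
        raise ValueError("regions must map >= 2 labels to 'cortex'/'noncortex'")

    rng = np.random.default_rng(seed)
    individuals = [f"Y{i+1}" for i in range(n_young)] + [f"A{i+1}" for i in range(n_aged)]
    age_group = {ind: ("young" if ind.startswith("Y") else "aged") for ind in individuals}
    sexes = {ind: ("M" if i % 2 == 0 else "F") for i, ind in enumerate(individuals)}

    drop = set(dropouts or [])
    rows = []
    for ind in individuals:
        for region, rclass in regions.items():
            for hemi in hemispheres:
                if (ind, region, hemi) in drop:
                    continue
                rows.append(
                    {
                        "sample_id": f"{ind}_{region}_{hemi}",
                        "individual": ind,
                        "age_group": age_group[ind],
                        "sex": sexes[ind],
                        "region": region,
                        "region_class": regions[region],
                        "hemisphere": hemi,
                        "batch": f"B{rng.integers(n_batches) + 1}",
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id")
    n = len(samples)

    # Latent per-sample quality factor drives all metrics coherently; the
    # normalization stage later recovers it as the leading surrogate variable.
    q = rng.normal(0.0, 1.0, size=n)
    samples["rin"] = np.clip(rng.normal(8.5, 0.7, size=n), 0.0, 10.0)
    samples["quality_factor"] = q
    for metric in QUALITY_METRICS:
        mu, sd = _METRIC_SCALE[metric]
        direction = -1.0 if metric in METRICS_BAD_HIGH else 1.0
        noise = rng.normal(0.0, 0.5 * sd, size=n)
        samples[metric] = mu + direction * q * sd * np.sqrt(0.75) + noise

    if low_quality_fraction > 0:
        n_bad = int(round(low_quality_fraction * n))
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        for i in bad_idx:
            if rng.random() < 0.5:
                samples.iloc[i, samples.columns.get_loc("rin")] = rng.uniform(2.0, 5.0)
            else:
                metrics = list(rng.choice(QUALITY_METRICS, size=rng.integers(2, 4), replace=False))
                for metric in metrics:
                    mu, sd = _METRIC_SCALE[metric]
                    shift = rng.uniform(3.0, 5.0) * sd
                    col = samples.columns.get_loc(metric)
                    if metric in METRICS_BAD_HIGH:
                        samples.iloc[i, col] = mu + shift
                    else:
                        samples.iloc[i, col] = mu - shift

    return StudyDesign(samples=samples, regions=dict(regions))


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``r_young`` / ``r_aged`` are the target intra-module Pearson
    correlations (on latent log expression) per age group; unequal values
    plant a connectivity gain or loss.  ``n_hubs`` genes are coupled to
    the module's latent factor almost deterministically in both groups;
    ``n_aged_specific_hubs`` additional genes are tightly coupled in the
    aged group only.
    """

    size: int
    r_young: float = 0.5
    r_aged: float = 0.5
    n_hubs: int = 0
    n_aged_specific_hubs: int = 0

    def __post_init__(self) -> None:
        for r in (self.r_young, self.r_aged):
            if not 0.0 <= r < 1.0:
                raise ValueError("module correlation targets must lie in [0, 1)")
        if self.n_hubs + self.n_aged_specific_hubs > self.size:
            raise ValueError("more hub genes requested than module members")


@dataclass(frozen=True)
class RegionEffect:
    """Extra expression offset restricted to one region (optionally one group)."""

    region: str
    n_genes: int
    log2fc: float
    group: str | None = None  # None: both groups


@dataclass
class TruthParams:
    """Generator settings: what to plant and how noisy to be.

    Effect sizes are in log2 units unless noted.  Defaults describe a
    moderate-depth bulk RNA-seq experiment with realistic library-size
    spread (CV ~0.3) and log-normal gene-wise NB dispersion.
    """

    n_genes: int = 2000
    mean_library_size: float = 2.0e5
    library_size_cv: float = 0.3
    baseline_log2_sd: float = 1.5
    dispersion_log_mean: float = float(np.log(0.08))
    dispersion_log_sd: float = 0.5

    modules: tuple[ModuleSpec, ...] = ()
    module_signal_sd: float = 1.0      # log2 sd of the module component
    module_expr_boost: float = 0.5     # log2 bump so module genes are well measured

    n_degs: int = 0
    deg_fc: float = 1.5                # linear fold change, aged vs young
    deg_from_celltype: str | None = None  # draw DEGs from one cell-type set

    region_effects: tuple[RegionEffect, ...] = ()

    # Target inter-region correlation of log-expression profiles per group
    # (None: regions share all gene baselines, correlation near 1).  Planted
    # by per-(gene, region) offsets whose variance is set against the
    # baseline variance: v = baseline_var * (1 - r) / r.
    region_profile_r_young: float | None = None
    region_profile_r_aged: float | None = None
    # Per-(gene, region, hemisphere) noise, planting hemispheric asymmetry.
    hemisphere_noise_sd_young: float = 0.0
    hemisphere_noise_sd_aged: float = 0.0

    n_exon_genes: int = 0
    exon_range: tuple[int, int] = (3, 8)
    n_deus: int = 0
    deu_usage_young: float = 0.3
    deu_usage_aged: float = 0.5

    batch_effect_sd: float = 0.0
    sex_effect_sd: float = 0.0
    quality_effect_sd: float = 0.0
    gc_bias_sd: float = 0.0

    n_celltype_genes: int = 0          # per cell type, 5 types


_CELL_TYPES = ("neuron", "microglia", "astrocyte", "oligodendrocyte", "endothelial")


@dataclass
class GroundTruth:
    """Record of every planted effect, for recovery scoring.

    Invariants: hub genes are members of their module; aged-specific hubs
    are hubs of the aged network only; DEG true fold changes exceed 1 in
    magnitude by construction.
    """

    deg_global: dict[str, dict] = field(default_factory=dict)
    deg_by_region: dict[str, list[str]] = field(default_factory=dict)
    deu: list[dict] = field(default_factory=list)
    module_membership: dict[str, str] = field(default_factory=dict)
    module_connectivity: dict[str, dict] = field(default_factory=dict)
    hub_genes: dict[str, list[str]] = field(default_factory=dict)
    aged_specific_hubs: dict[str, list[str]] = field(default_factory=dict)
    covariate_betas: pd.DataFrame | None = None
    celltype_sets: dict[str, list[str]] = field(default_factory=dict)
    gene_annotation: pd.DataFrame | None = None

    def deu_genes(self) -> set[str]:
        return {rec["gene"] for rec in self.deu}

    def to_json(self, path) -> None:
        payload = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, pd.DataFrame):
                value = value.to_dict(orient="index")
            payload[f.name] = value
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: Var = mu + alpha * mu^2 (alpha broadcast over genes)."""
    alpha = np.broadcast_to(alpha, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    lam = np.where(
        tiny, mu, rng.gamma(np.maximum(1.0 / np.maximum(alpha, 1e-8), 1e-12), 1.0) * mu * alpha
    )
    out = rng.poisson(np.where(tiny, mu, lam))
    return out.astype(np.int64)


def simulate_counts(
    design: StudyDesign, params: TruthParams, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a gene x sample count matrix and the ground truth behind it.

    Returns ``(counts, truth)`` where ``counts`` is an integer DataFrame
    with gene ids as rows and ``design`` sample ids as columns, and
    ``truth.gene_annotation`` carries per-gene GC fraction and length for
    the normalization stage.
    """
    rng = np.random.default_rng(seed)
    n_genes = params.n_genes
    samples = design.samples
    n = len(samples)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])

    module_sizes = sum(m.size for m in params.modules)
    if module_sizes > n_genes:
        raise ValueError("module sizes exceed gene count")

    truth = GroundTruth()

    # --- gene annotation -------------------------------------------------
    gc = rng.beta(8, 8, size=n_genes)                      # centered near 0.5
    length = np.exp(rng.normal(np.log(2500), 0.6, size=n_genes))
    truth.gene_annotation = pd.DataFrame(
        {"gc_fraction": gc, "length": length.round(0)}, index=genes
    )

    baseline = rng.normal(0.0, params.baseline_log2_sd, size=n_genes)
    alpha = np.exp(rng.normal(params.dispersion_log_mean, params.dispersion_log_sd, size=n_genes))

    aged = (samples["age_group"] == "aged").to_numpy()
    log2mu = np.tile(baseline[:, None], (1, n))

    # --- modules ---------------------------------------------------------
    cursor = 0
    for mi, spec in enumerate(params.modules):
        name = f"module_{mi + 1}"
        idx = np.arange(cursor, cursor + spec.size)
        cursor += spec.size
        member_genes = genes[idx]
        truth.module_membership.update({g: name for g in member_genes})
        shift = "gain" if spec.r_aged > spec.r_young else ("loss" if spec.r_aged < spec.r_young else "none")
        truth.module_connectivity[name] = {
            "r_young": spec.r_young,
            "r_aged": spec.r_aged,
            "shift": shift,
        }
        factor = rng.normal(0.0, 1.0, size=n)
        sig = params.module_signal_sd
        # Compensate the known measurement-noise attenuation: counts add
        # roughly (alpha + 1/mu) / ln(2)^2 of log2 variance on top of the
        # latent signal, so the latent correlation is inflated so that the
        # *realized* log-expression correlation lands on the target.
        mu_typical = params.mean_library_size / n_genes * 2.0**params.module_expr_boost
        noise_var = (0.02 + 1.0 / max(mu_typical, 1.0)) / np.log(2.0) ** 2
        inflate = (sig**2 + noise_var) / sig**2
        r_y = min(spec.r_young * inflate, 0.97)
        r_a = min(spec.r_aged * inflate, 0.97)
        r = np.where(aged, r_a, r_y)                       # per-sample target r
        idio = rng.normal(0.0, 1.0, size=(spec.size, n))
        contrib = sig * (np.sqrt(r)[None, :] * factor[None, :] + np.sqrt(1.0 - r)[None, :] * idio)

        hubs = list(member_genes[: spec.n_hubs])
        aspec = list(member_genes[spec.n_hubs : spec.n_hubs + spec.n_aged_specific_hubs])
        # Hubs track the factor almost perfectly in both groups.
        for j in range(spec.n_hubs):
            contrib[j] = sig * (0.995 * factor + np.sqrt(1 - 0.995**2) * idio[j])
        # Aged-specific hubs track it only in aged samples.
        for j in range(spec.n_hubs, spec.n_hubs + spec.n_aged_specific_hubs):
            tight = sig * (0.995 * factor + np.sqrt(1 - 0.995**2) * idio[j])
            loose = sig * rng.normal(0.0, 1.0, size=n)
            contrib[j] = np.where(aged, tight, loose)
        truth.hub_genes[name] = hubs + aspec
        truth.aged_specific_hubs[name] = aspec

        log2mu[idx] += contrib + params.module_expr_boost
        alpha[idx] = np.minimum(alpha[idx], 0.02)          # keep module genes well measured

    # --- cell-type specific sets ----------------------------------------
    free = np.arange(cursor, n_genes)
    if params.n_celltype_genes > 0:
        need = 5 * params.n_celltype_genes
        if need > len(free):
            raise ValueError("not enough genes outside modules for cell-type sets")
        picked = rng.choice(free, size=need, replace=False)
        for t, ct in enumerate(_CELL_TYPES):
            block = picked[t * params.n_celltype_genes : (t + 1) * params.n_celltype_genes]
            truth.celltype_sets[ct] = [str(g) for g in genes[block]]

    # --- DEGs ------------------------------------------------------------
    if params.n_degs > 0:
        if params.deg_from_celltype is not None:
            pool = [np.where(genes == g)[0][0] for g in truth.celltype_sets[params.deg_from_celltype]]
            pool = np.array(pool)
        else:
            pool = free
        if params.n_degs > len(pool):
            raise ValueError("not enough eligible genes for requested DEGs")
        deg_idx = rng.choice(pool, size=params.n_degs, replace=False)
        directions = rng.choice([-1.0, 1.0], size=params.n_degs)
        effect = directions * np.log2(params.deg_fc)
        log2mu[deg_idx[:, None], np.where(aged)[0][None, :]] += effect[:, None]
        for g, d in zip(genes[deg_idx], directions):
            truth.deg_global[str(g)] = {"direction": "up" if d > 0 else "down", "fc": params.deg_fc}

    # --- region-restricted effects --------------------------------------
    for eff in params.region_effects:
        mask = (samples["region"] == eff.region).to_numpy()
        if eff.group is not None:
            mask &= (samples["age_group"] == eff.group).to_numpy()
        ridx = rng.choice(free, size=eff.n_genes, replace=False)
        log2mu[ridx[:, None], np.where(mask)[0][None, :]] += eff.log2fc
        truth.deg_by_region.setdefault(eff.region, []).extend(str(g) for g in genes[ridx])

    # --- region divergence and hemispheric asymmetry ---------------------
    baseline_var = params.baseline_log2_sd**2
    for group, rtarget in (("young", params.region_profile_r_young),
                           ("aged", params.region_profile_r_aged)):
        if rtarget is None:
            continue
        if not 0.0 < rtarget <= 1.0:
            raise ValueError("region profile correlation target must lie in (0, 1]")
        sd = np.sqrt(baseline_var * (1.0 - rtarget) / rtarget)
        gmask = (samples["age_group"] == group).to_numpy()
        for region in design.regions:
            cols = gmask & (samples["region"] == region).to_numpy()
            if cols.any():
                log2mu[:, cols] += rng.normal(0.0, sd, size=n_genes)[:, None]
    for group, sd in (("young", params.hemisphere_noise_sd_young),
                      ("aged", params.hemisphere_noise_sd_aged)):
        if sd <= 0:
            continue
        gmask = (samples["age_group"] == group).to_numpy()
        for region in design.regions:
            for hemi in samples["hemisphere"].unique():
                cols = gmask & (samples["region"] == region).to_numpy() \
                    & (samples["hemisphere"] == hemi).to_numpy()
                if cols.any():
                    log2mu[:, cols] += rng.normal(0.0, sd, size=n_genes)[:, None]

    # --- covariates ------------------------------------------------------
    betas = pd.DataFrame(0.0, index=genes, columns=["batch", "sex", "quality"])
    if params.batch_effect_sd > 0:
        b = rng.normal(0.0, params.batch_effect_sd, size=n_genes)
        ind = (samples["batch"] != samples["batch"].iloc[0]).to_numpy().astype(float)
        log2mu += b[:, None] * ind[None, :]
        betas["batch"] = b
    if params.sex_effect_sd > 0:
        b = rng.normal(0.0, params.sex_effect_sd, size=n_genes)
        ind = (samples["sex"] == "F").to_numpy().astype(float)
        log2mu += b[:, None] * ind[None, :]
        betas["sex"] = b
    if params.quality_effect_sd > 0:
        b = rng.normal(0.0, params.quality_effect_sd, size=n_genes)
        qf = samples["quality_factor"].to_numpy()
        log2mu += b[:, None] * qf[None, :]
        betas["quality"] = b
    truth.covariate_betas = betas

    # --- GC bias ---------------------------------------------------------
    if params.gc_bias_sd > 0:
        h = (gc - 0.5) ** 2
        h = (h - h.mean()) / h.std()
        c = rng.normal(0.0, params.gc_bias_sd, size=n)
        log2mu += h[:, None] * c[None, :]

    # --- library size and sampling --------------------------------------
    sigma_ln = np.sqrt(np.log(1.0 + params.library_size_cv**2))
    libsize = params.mean_library_size * np.exp(rng.normal(0.0, sigma_ln, size=n) - sigma_ln**2 / 2)
    rel = np.exp2(log2mu)
    # Normalize by the dataset-wide mean total abundance rather than each
    # sample's own total: per-sample renormalization would leak planted
    # factors into every gene's mean (compositional coupling) and attenuate
    # the planted correlations.  Realized totals still track libsize.
    denom = rel.sum(axis=0).mean()
    mu = rel / denom * libsize[None, :]
    counts = _nb_counts(rng, mu, alpha[:, None])

    counts_df = pd.DataFrame(counts, index=genes, columns=samples.index)
    return counts_df, truth


def simulate_exon_counts(
    counts: pd.DataFrame,
    design: StudyDesign,
    params: TruthParams,
    truth: GroundTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Partition gene counts into exon counts by per-group multinomial usage.

    The first ``params.n_exon_genes`` genes receive an exon structure.
    For ``params.n_deus`` of them, the first exon's usage fraction moves
    from ``deu_usage_young`` to ``deu_usage_aged`` in the aged group; the
    remaining mass is spread over the other exons in fixed proportions.
    Returns a DataFrame indexed by (gene_id, exon_id).
    """
    rng = np.random.default_rng(seed)
    n_exon_genes = min(params.n_exon_genes, counts.shape[0])
    if params.n_deus > n_exon_genes:
        raise ValueError("more DEU genes requested than exon-bearing genes")
    aged = (design.samples["age_group"] == "aged").to_numpy()
    exon_genes = list(counts.index[:n_exon_genes])
    deu_genes = set(rng.choice(exon_genes, size=params.n_deus, replace=False))

    rows, index = [], []
    lo, hi = params.exon_range
    for gene in exon_genes:
        k = int(rng.integers(lo, hi + 1))
        base = rng.dirichlet(np.full(k, 5.0))
        usage_young = base.copy()
        usage_aged = base.copy()
        if gene in deu_genes:
            usage_young[0] = params.deu_usage_young
            usage_aged[0] = params.deu_usage_aged
            rest = base[1:] / base[1:].sum()
            usage_young[1:] = (1 - params.deu_usage_young) * rest
            usage_aged[1:] = (1 - params.deu_usage_aged) * rest
            truth.deu.append(
                {
                    "gene": str(gene),
                    "exon": f"E001",
                    "usage_young": params.deu_usage_young,
                    "usage_aged": params.deu_usage_aged,
                }
            )
        totals = counts.loc[gene].to_numpy()
        mat = np.empty((k, len(totals)), dtype=np.int64)
        for j, total in enumerate(totals):
            usage = usage_aged if aged[j] else usage_young
            mat[:, j] = rng.multinomial(int(total), usage)
        for e in range(k):
            index.append((str(gene), f"E{e + 1:03d}"))
            rows.append(mat[e])

    exon_counts = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, counts.shape[1]), dtype=np.int64),
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "exon_id"]),
        columns=counts.columns,
    )
    return exon_counts


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_counts_mtx(counts: pd.DataFrame, prefix: str) -> None:
    """Write MatrixMarket triple: ``<prefix>.mtx``, ``.rows``, ``.cols``."""
    from scipy import io as sio
    from scipy import sparse

    sio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts.to_numpy()))
    with open(f"{prefix}.rows", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(f"{prefix}.cols", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")
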