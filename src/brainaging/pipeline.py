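"""End-to-end orchestration: config, stage sequencing, manifest, report.

A run executes, in order: simulate (optional) -> sample QC -> gene
filtering -> normalization and covariate adjustment -> connectivity
comparison -> differential expression -> differential exon usage ->
module detection with MDC -> key-driver discovery.  Every stage logs its
parameters and output files (with content hashes) to a JSON manifest, so
re-running with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from brainaging import (
    coexpression,
    connectivity,
    diffexpr,
    keydrivers,
    normalize,
    qc,
    splicing,
    synthdata,
)

__all__ = ["RunConfig", "run_pipeline", "summarize_report", "summary_fractions"]


@dataclass
class RunConfig:
    """All pipeline settings; defaults give a small, minutes-scale run."""

    out_dir: str = "pipeline_out"
    seed: int = 0

    # synthetic input (used when no counts path is given)
    n_young: int = 4
    n_aged: int = 3
    n_cortex_regions: int = 5
    n_noncortex_regions: int = 3
    n_genes: int = 1200
    n_degs: int = 60
    deg_fc: float = 2.0
    n_modules_gain: int = 1
    n_modules_null: int = 2
    module_size: int = 50
    r_young_null: float = 0.55
    r_gain_young: float = 0.25
    r_gain_aged: float = 0.75
    n_exon_genes: int = 120
    n_deus: int = 30
    batch_effect_sd: float = 0.3
    sex_effect_sd: float = 0.2
    quality_effect_sd: float = 0.2
    gc_bias_sd: float = 0.3
    low_quality_fraction: float = 0.05
    n_celltype_genes: int = 40

    # QC
    rin_cutoff: float = 5.0
    z_cut: float = 2.0
    min_count: int = 10
    min_fraction: float = 0.8

    # DE / DEU
    p_cut: float = 0.05
    fc_cut: float = 1.5
    deu_p_cut: float = 0.01

    # network ("auto" = scale-free power selection; 6 is the conventional
    # unsigned-network default and more stable on small synthetic runs)
    power: int | str = 6
    min_module_size: int = 24
    cut_height: float = 0.97
    merge_height: float = 0.25
    mdc_n_perm: int = 200
    mdc_q_cut: float = 0.05

    # drivers
    dpi_tolerance: float = 0.15
    hub_top_fraction: float = 0.05
    n_hops: int = 2
    mi_n_perm: int = 200
    mi_alpha: float = 0.05

    stages: tuple[str, ...] = (
        "simulate",
        "qc",
        "normalize",
        "connectivity",
        "de",
        "splicing",
        "network",
        "drivers",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def truth_params(self) -> synthdata.TruthParams:
        modules = [
            synthdata.ModuleSpec(
                size=self.module_size,
                r_young=self.r_gain_young,
                r_aged=self.r_gain_aged,
                n_hubs=1,
                n_aged_specific_hubs=1,
            )
            for _ in range(self.n_modules_gain)
        ] + [
            synthdata.ModuleSpec(
                size=self.module_size,
                r_young=self.r_young_null,
                r_aged=self.r_young_null,
                n_hubs=1,
            )
            for _ in range(self.n_modules_null)
        ]
        return synthdata.TruthParams(
            n_genes=self.n_genes,
            modules=tuple(modules),
            n_degs=self.n_degs,
            deg_fc=self.deg_fc,
            n_exon_genes=self.n_exon_genes,
            n_deus=self.n_deus,
            batch_effect_sd=self.batch_effect_sd,
            sex_effect_sd=self.sex_effect_sd,
            quality_effect_sd=self.quality_effect_sd,
            gc_bias_sd=self.gc_bias_sd,
            n_celltype_genes=self.n_celltype_genes,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summary_fractions(counts: dict[str, float]) -> dict[str, float]:
    """Headline percentages from component counts.

    Given any subset of the count pairs below, returns the derived
    quantities (percentages on the 0-100 scale, rounded to one decimal):

    * ``detected_genes`` / ``annotated_genes`` -> ``detected_gene_pct``
    * ``cortex_degs`` / ``cortex_expressed`` -> ``cortex_deg_pct``
    * ``noncortex_degs`` / ``noncortex_expressed`` -> ``noncortex_deg_pct``
    * ``gain_modules`` & ``unchanged_modules`` / ``total_modules``
      -> ``gain_module_pct``, ``unchanged_module_pct``
    * ``qc_removed`` / ``initial_samples`` -> ``qc_removed_pct`` and
      ``post_qc_samples``
    """
    out: dict[str, float] = {}

    def pct(num: str, den: str, name: str) -> None:
        if num in counts and den in counts and counts[den]:
            out[name] = round(100.0 * counts[num] / counts[den], 1)

    pct("detected_genes", "annotated_genes", "detected_gene_pct")
    pct("cortex_degs", "cortex_expressed", "cortex_deg_pct")
    pct("noncortex_degs", "noncortex_expressed", "noncortex_deg_pct")
    pct("gain_modules", "total_modules", "gain_module_pct")
    pct("unchanged_modules", "total_modules", "unchanged_module_pct")
    pct("qc_removed", "initial_samples", "qc_removed_pct")
    if "initial_samples" in counts and "qc_removed" in counts:
        out["post_qc_samples"] = counts["initial_samples"] - counts["qc_removed"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
        "summary": {},
    }
    manifest["config"]["stages"] = list(config.stages)

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    rng_seed = config.seed

    # --- simulate --------------------------------------------------------
    design = synthdata.make_design(
        n_young=config.n_young,
        n_aged=config.n_aged,
        regions=synthdata.default_regions(config.n_cortex_regions, config.n_noncortex_regions),
        low_quality_fraction=config.low_quality_fraction,
        seed=rng_seed,
    )
    params = config.truth_params()
    counts, truth = synthdata.simulate_counts(design, params, seed=rng_seed + 1)
    exon_counts = synthdata.simulate_exon_counts(counts, design, params, truth, seed=rng_seed + 2)
    if "simulate" in config.stages:
        synthdata.write_counts_tsv(counts, out / "counts.tsv")
        design.samples.to_csv(out / "samples.tsv", sep="\t")
        truth.to_json(out / "ground_truth.json")
        record("counts", out / "counts.tsv")
        record("samples", out / "samples.tsv")
        record("ground_truth", out / "ground_truth.json")
        manifest["stages"]["simulate"] = {"n_samples": design.n_samples, "n_genes": config.n_genes}

    # --- qc --------------------------------------------------------------
    verdicts = qc.qc_samples(design.samples, rin_cutoff=config.rin_cutoff, z_cut=config.z_cut)
    kept = verdicts.retained
    meta = design.samples.loc[kept]
    gene_filter = qc.filter_low_expression_genes(
        counts[kept],
        strata=meta["region_class"],
        min_count=config.min_count,
        min_fraction=config.min_fraction,
    )
    fcounts = gene_filter.counts
    if "qc" in config.stages:
        verdicts.table.to_csv(out / "qc_verdicts.tsv", sep="\t")
        record("qc_verdicts", out / "qc_verdicts.tsv")
        manifest["stages"]["qc"] = {
            "initial_samples": int(design.n_samples),
            "removed_samples": int(len(verdicts.removed)),
            "retained_samples": int(len(kept)),
            "annotated_genes": int(counts.shape[0]),
            "detected_genes": int(fcounts.shape[0]),
        }

    # --- normalize -------------------------------------------------------
    expr = normalize.gc_depth_normalize(fcounts, truth.gene_annotation, metadata=meta)
    surro = normalize.compute_seq_surrogates(meta)
    covariates = pd.concat(
        [meta[["batch", "sex"]], surro.table], axis=1
    )
    expr = normalize.adjust_covariates(expr, covariates)
    if "normalize" in config.stages:
        expr.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
        record("expression", out / "expression.tsv")
        manifest["stages"]["normalize"] = {
            "transforms": expr.transforms,
            "seq_surrogate_variance": list(surro.variance_explained),
        }

    # --- connectivity ----------------------------------------------------
    if "connectivity" in config.stages:
        conn = {}
        for scope in ("cortex", "noncortex"):
            young = connectivity.region_profiles(expr, "young", scope=scope)
            aged = connectivity.region_profiles(expr, "aged", scope=scope)
            cy = connectivity.pairwise_correlation(young)
            ca = connectivity.pairwise_correlation(aged)
            verdict = connectivity.compare_connectivity(cy, ca)
            cy.to_csv(out / f"connectivity_{scope}_young.tsv", sep="\t")
            ca.to_csv(out / f"connectivity_{scope}_aged.tsv", sep="\t")
            record(f"connectivity_{scope}_young", out / f"connectivity_{scope}_young.tsv")
            record(f"connectivity_{scope}_aged", out / f"connectivity_{scope}_aged.tsv")
            conn[scope] = {
                "mwu_p": verdict.p_value,
                "direction": verdict.direction,
                "attenuated_in_aged": bool(verdict.attenuated_in_aged),
            }
        manifest["stages"]["connectivity"] = conn

    # --- differential expression ----------------------------------------
    deg_sets: dict[str, set] = {}
    de_info: dict = {}
    for scope in ("cortex", "noncortex"):
        cols = meta.index[meta["region_class"] == scope]
        scope_genes = gene_filter.retained_by_stratum.get(scope, fcounts.index)
        res = diffexpr.de_test(
            fcounts.loc[scope_genes, cols], meta.loc[cols, "age_group"]
        )
        degs = diffexpr.call_degs(res, p_cut=config.p_cut, fc_cut=config.fc_cut)
        deg_sets[scope] = set(degs)
        de_info[scope] = {"expressed": int(len(scope_genes)), "degs": int(len(degs))}
        if "de" in config.stages:
            res.table.to_csv(out / f"de_{scope}.tsv", sep="\t", index_label="gene_id")
            record(f"de_{scope}", out / f"de_{scope}.tsv")
    if "de" in config.stages:
        universe = set(fcounts.index)
        de_info["overlap_rate"] = diffexpr.overlap_rate(deg_sets["cortex"], deg_sets["noncortex"])
        if deg_sets["cortex"] and deg_sets["noncortex"]:
            _, p = diffexpr.overlap_significance(
                deg_sets["cortex"], deg_sets["noncortex"], universe
            )
            de_info["overlap_fisher_p"] = p
        manifest["stages"]["de"] = de_info

    # --- splicing --------------------------------------------------------
    if "splicing" in config.stages and len(exon_counts):
        exon_kept = exon_counts[kept]
        deu_res = splicing.exon_usage_test(exon_kept, meta["age_group"])
        deu_genes = splicing.call_deus(deu_res, p_cut=config.deu_p_cut)
        deu_res.table.to_csv(out / "deu.tsv", sep="\t")
        record("deu", out / "deu.tsv")
        manifest["stages"]["splicing"] = {
            "tested_genes": int(deu_res.table.index.get_level_values("gene_id").nunique()),
            "deu_genes": int(len(deu_genes)),
        }

    # --- network ---------------------------------------------------------
    moduleset = None
    mdc_table = None
    if "network" in config.stages:
        aged_cols = meta.index[meta["age_group"] == "aged"]
        young_cols = meta.index[meta["age_group"] == "young"]
        expr_region = coexpression.correct_region_covariate(expr, meta["region"])
        aged_expr = expr_region.values[aged_cols]
        young_expr = expr_region.values[young_cols]
        power = (
            coexpression.pick_soft_threshold(aged_expr)
            if config.power == "auto"
            else int(config.power)
        )
        moduleset = coexpression.detect_modules(
            aged_expr,
            power=power,
            min_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_height=config.merge_height,
        )
        mdc_table = coexpression.mdc_significance(
            moduleset,
            young_expr,
            aged_expr,
            n_perm=config.mdc_n_perm,
            q_cut=config.mdc_q_cut,
            seed=config.seed + 3,
        )
        moduleset.membership.rename("module").to_csv(
            out / "modules.tsv", sep="\t", index_label="gene_id"
        )
        mdc_table.to_csv(out / "mdc.tsv", sep="\t", index_label="module")
        record("modules", out / "modules.tsv")
        record("mdc", out / "mdc.tsv")
        n_modules = len(moduleset.modules())
        n_gain = int((mdc_table["verdict"] == "gain").sum())
        manifest["stages"]["network"] = {
            "power": int(power),
            "n_modules": n_modules,
            "gain_modules": n_gain,
            "loss_modules": int((mdc_table["verdict"] == "loss").sum()),
            "unchanged_modules": int((mdc_table["verdict"] == "none").sum()),
        }

    # --- drivers ---------------------------------------------------------
    if "drivers" in config.stages and moduleset is not None and len(moduleset.modules()):
        # focus on the most connectivity-gaining module (highest log2 MDC)
        focus = mdc_table["log2_mdc"].idxmax()
        genes = moduleset.genes_of(focus)
        aged_cols = meta.index[meta["age_group"] == "aged"]
        young_cols = meta.index[meta["age_group"] == "young"]
        net_y = keydrivers.build_mi_network(
            expr.values.loc[genes, young_cols],
            group="young",
            tolerance=config.dpi_tolerance,
            n_perm=config.mi_n_perm,
            alpha=config.mi_alpha,
            seed=config.seed + 4,
        )
        net_a = keydrivers.build_mi_network(
            expr.values.loc[genes, aged_cols],
            group="aged",
            tolerance=config.dpi_tolerance,
            n_perm=config.mi_n_perm,
            alpha=config.mi_alpha,
            seed=config.seed + 5,
        )
        report = keydrivers.key_driver_report(
            net_y, net_a, module=focus,
            top_fraction=config.hub_top_fraction, n_hops=config.n_hops,
        )
        report.table.to_csv(out / "key_drivers.tsv", sep="\t", index_label="gene_id")
        record("key_drivers", out / "key_drivers.tsv")
        manifest["stages"]["drivers"] = {
            "module": focus,
            "hubs_aged": sorted(report.hubs_aged),
            "aged_specific_hubs": sorted(report.aged_specific),
            "top_nhnn": list(report.table.index[:5]),
        }

    # --- summary + ground-truth recovery ---------------------------------
    summary_counts = {
        "annotated_genes": counts.shape[0],
        "detected_genes": fcounts.shape[0],
        "initial_samples": design.n_samples,
        "qc_removed": len(verdicts.removed),
        "cortex_degs": de_info.get("cortex", {}).get("degs", 0),
        "cortex_expressed": de_info.get("cortex", {}).get("expressed", 0),
        "noncortex_degs": de_info.get("noncortex", {}).get("degs", 0),
        "noncortex_expressed": de_info.get("noncortex", {}).get("expressed", 0),
    }
    if "network" in manifest["stages"]:
        st = manifest["stages"]["network"]
        summary_counts.update(
            total_modules=st["n_modules"],
            gain_modules=st["gain_modules"],
            unchanged_modules=st["unchanged_modules"],
        )
    manifest["summary"] = {
        "counts": {k: int(v) for k, v in summary_counts.items()},
        "fractions": summary_fractions(summary_counts),
    }
    if truth is not None and moduleset is not None:
        manifest["summary"]["recovery"] = _recovery_summary(truth, moduleset, mdc_table, deg_sets)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _recovery_summary(truth, moduleset, mdc_table, deg_sets) -> dict:
    """Score recovery of planted structure against the ground truth."""
    from sklearn.metrics import adjusted_rand_score

    out: dict = {}
    if truth.module_membership:
        genes = [g for g in moduleset.membership.index if g in truth.module_membership]
        noise = [g for g in moduleset.membership.index if g not in truth.module_membership]
        true_labels = [truth.module_membership[g] for g in genes] + ["noise"] * len(noise)
        found = list(moduleset.membership.loc[genes]) + list(moduleset.membership.loc[noise])
        out["module_ari"] = float(adjusted_rand_score(true_labels, found))
    if truth.deg_global:
        planted = set(truth.deg_global)
        called = set().union(*deg_sets.values()) if deg_sets else set()
        out["deg_recall"] = len(planted & called) / len(planted) if planted else float("nan")
    if mdc_table is not None and truth.module_connectivity:
        gains = {m for m, rec in truth.module_connectivity.items() if rec["shift"] == "gain"}
        if gains:
            # map planted modules to detected ones by best overlap
            hits = 0
            for m in gains:
                planted_genes = {g for g, mm in truth.module_membership.items() if mm == m}
                best, best_ov = None, 0
                for d in moduleset.modules():
                    ov = len(planted_genes & set(moduleset.genes_of(d)))
                    if ov > best_ov:
                        best, best_ov = d, ov
                if best is not None and mdc_table.loc[best, "verdict"] == "gain":
                    hits += 1
            out["gain_module_detection"] = hits / len(gains)
    return out


def summarize_report(manifest: dict) -> str:
    """Human-readable Markdown digest of a run manifest."""
    lines = ["# Pipeline run report", ""]
    lines.append(f"- seed: {manifest.get('seed')}")
    cfg_hash = hashlib.sha256(
        json.dumps(manifest.get("config", {}), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    lines.append(f"- config hash: {cfg_hash}")
    lines.append("")
    stages = manifest.get("stages", {})
    for name, info in stages.items():
        lines.append(f"## {name}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    summary = manifest.get("summary", {})
    if summary:
        lines.append("## summary")
        for section, vals in summary.items():
            lines.append(f"### {section}")
            if isinstance(vals, dict):
                for k, v in vals.items():
                    lines.append(f"- {k}: {v}")
            lines.append("")
    return "\n".join(lines)
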