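"""Sample QC (RIN cutoff + signed z-score outliers) and gene filtering.

Simulates a design where 7% of libraries are degraded, applies the two
sample-level rules, then keeps genes with >= 10 counts in >= 80% of the
samples of either stratum (cortex / non-cortex).
"""

from brainaging import qc, synthdata as sd

design = sd.make_design(n_young=4, n_aged=3,
                        regions=sd.default_regions(5, 3),
                        low_quality_fraction=0.07, seed=4)
counts, _ = sd.simulate_counts(design, sd.TruthParams(n_genes=1500), seed=5)

verdicts = qc.qc_samples(design.samples, rin_cutoff=5.0, z_cut=2.0)
n_rin = (~verdicts.table["rin_pass"]).sum()
n_out = (verdicts.table["rin_pass"] & ~verdicts.table["retained"]).sum()
print(f"samples: {design.n_samples} sequenced, {len(verdicts.retained)} retained "
      f"({n_rin} failed RIN <= 5, {n_out} had >1 quality-metric outlier)")

kept = counts[verdicts.retained]
strata = design.samples.loc[verdicts.retained, "region_class"]
genes = qc.filter_low_expression_genes(kept, strata=strata)
pct = 100 * len(genes.detected) / counts.shape[0]
print(f"genes: {len(genes.detected)}/{counts.shape[0]} detected ({pct:.1f}%); "
      f"cortex stratum {len(genes.retained_by_stratum['cortex'])}, "
      f"non-cortex {len(genes.retained_by_stratum['noncortex'])}")
# A retained sample passed both rules; a detected gene is expressed in at
# least one stratum at the 10-count / 80%-of-samples level.
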