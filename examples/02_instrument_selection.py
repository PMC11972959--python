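"""Variant QC, per-SNP GWAS, LD clumping and the weighted risk score.

Reproduces the instrument-selection stage: drop variants failing call-rate
/ Hardy-Weinberg / MAF rules, run an age- and sex-adjusted additive GWAS,
thin the hits to approximately independent variants, and build the wGRS.
"""

import numpy as np

from mrtraj import (SimulationConfig, bonferroni_threshold, build_wgrs,
                    generate_cohort, ld_clump, qc_filter, run_gwas)

panel = generate_cohort(SimulationConfig(n_subjects=3000, missing_rate=0.01,
                                         seed=11))
qc = qc_filter(panel)
print(f"QC: kept {len(qc.kept_variants)}/{panel.n_snps} variants, "
      f"dropped {qc.n_subjects_dropped} subjects")
reasons = qc.variant_report.loc[~qc.variant_report.kept, "reason"]
if len(reasons):
    print("  failure reasons:", reasons.value_counts().to_dict())

summ = run_gwas(panel, "fbs", variant_ids=qc.kept_variants)
print(f"GWAS (FBS ~ dosage + age + sex): "
      f"{(summ.p_value < 5e-8).sum()} genome-wide hits, "
      f"min p = {summ.p_value.min():.2e}")

inst = ld_clump(summ, panel, p_threshold=1e-4, phenotype="fbs")
print(f"clumping (r2<{inst.clump_r2}, window {inst.window_bp/1e6:.0f} Mb): "
      f"{len(inst)} instruments retained")

wgrs = build_wgrs(panel, inst)
print(f"wGRS: mean {wgrs.mean():.3f}, SD {wgrs.std():.3f} "
      f"(phenotype units; all weights oriented trait-increasing)")
print(f"Bonferroni threshold for {len(inst)} instruments: "
      f"{bonferroni_threshold(0.05, max(len(inst), 1)):.2e}")
# The wGRS aggregates the retained variants into one instrumental variable
# per subject; its variance determines the first-stage strength downstream.
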