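"""End-to-end orchestration: simulate -> QC/GWAS -> clump -> wGRS -> MR ->
trajectories -> survival, with logging, a manifest, and write-once artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import write_cohort
from .config import PipelineConfig
from .instruments import build_wgrs, ld_clump, qc_filter, run_gwas
from .mr import run_bidirectional
from .simulate import generate_cohort
from .survival import table2_report
from .trajectory import predict_series, select_model

log = logging.getLogger("mrtraj.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: PipelineConfig, out_dir: str | Path,
            seed: int | None = None) -> Path:
    """Run the full synthetic study; returns the artifact directory.

    The stage order mirrors the analysis: cohort simulation, variant QC and
    per-phenotype GWAS, LD clumping, wGRS construction, bidirectional MR,
    trajectory modeling of genetically predicted series, and the
    trajectory-to-incidence Cox report. Artifacts are written once each;
    the manifest records seeds, stage record counts and file hashes, so two
    runs with the same config and seed produce identical manifests.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng_seed = int(seed)
    counts: dict[str, object] = {}
    artifacts: list[Path] = []
    t0 = time.time()

    def _stage(name):
        log.info("stage %s", name)
        return name

    stage = _stage("simulate")
    try:
        panel = generate_cohort(config.sim, seed=rng_seed)
        cohort_dir = out / "cohort"
        artifacts += write_cohort(panel, cohort_dir)
        counts["simulate"] = {"subjects": panel.n_subjects,
                              "variants": panel.n_snps}
        log.info("simulated %d subjects x %d variants",
                 panel.n_subjects, panel.n_snps)

        stage = _stage("qc")
        qc = qc_filter(panel, call_rate=config.qc_call_rate,
                       hwe_p=config.qc_hwe_p, maf=config.qc_maf,
                       subject_missing=config.qc_subject_missing)
        qc.variant_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        artifacts.append(out / "qc_report.tsv")
        panel_qc = panel.subset_subjects(
            np.isin(panel.subject_ids, qc.kept_subjects))
        counts["qc"] = {"subjects_kept": len(qc.kept_subjects),
                        "subjects_dropped": qc.n_subjects_dropped,
                        "variants_kept": len(qc.kept_variants)}
        log.info("QC kept %d/%d variants, dropped %d subjects",
                 len(qc.kept_variants), panel.n_snps, qc.n_subjects_dropped)

        stage = _stage("gwas_clump_wgrs")
        instruments = {}
        wgrs = {}
        for pheno in ("fbs", "sbp"):
            summ = run_gwas(panel_qc, pheno,
                            covariates=config.gwas_covariates,
                            variant_ids=qc.kept_variants)
            summ.to_csv(out / f"gwas_{pheno}.tsv", sep="\t", index=False)
            artifacts.append(out / f"gwas_{pheno}.tsv")
            inst = ld_clump(summ, panel_qc, r2_threshold=config.clump_r2,
                            window_bp=config.clump_window_bp,
                            p_threshold=config.clump_p, phenotype=pheno)
            inst.to_tsv(out / f"instruments_{pheno}.tsv")
            artifacts.append(out / f"instruments_{pheno}.tsv")
            instruments[pheno] = inst
            wgrs[pheno] = build_wgrs(panel_qc, inst) if len(inst) else None
            counts[f"instruments_{pheno}"] = len(inst)
            log.info("%s: %d instruments after clumping", pheno, len(inst))

        stage = _stage("mr")
        if len(instruments["fbs"]) == 0 or len(instruments["sbp"]) == 0:
            raise RuntimeError("no instruments survived clumping; lower "
                               "clump_p for small synthetic panels")
        mr_report = run_bidirectional(
            panel_qc, instruments["fbs"], instruments["sbp"],
            n_boot=config.mr_n_boot, seed=rng_seed,
            exclude_shared=config.mr_exclude_shared)
        mr_report.to_tsv(out / "mr_report.tsv", out / "mr_diagnostics.tsv")
        artifacts += [out / "mr_report.tsv", out / "mr_diagnostics.tsv"]

        stage = _stage("trajectory")
        traj_json = {}
        assignments = {}
        for pheno in config.traj_phenotypes:
            series = predict_series(panel_qc, wgrs[pheno], pheno)
            best, table = select_model(
                series, k_range=config.traj_k_range,
                order_range=config.traj_orders, seed=rng_seed,
                n_restarts=config.traj_restarts)
            assign = best.assignments_frame()
            assign.to_csv(out / f"assignments_{pheno}.tsv", sep="\t",
                          index=False)
            artifacts.append(out / f"assignments_{pheno}.tsv")
            assignments[pheno] = assign
            traj_json[pheno] = {"selected": best.to_dict(),
                                "selection_table":
                                    table.to_dict(orient="records")}
            counts[f"trajectory_{pheno}"] = {
                "K": best.n_groups,
                "shares": best.mixing_proportions.tolist()}
            log.info("%s trajectories: K=%d, BIC=%.1f", pheno,
                     best.n_groups, best.bic)
        with open(out / "trajectory_fit.json", "w") as fh:
            json.dump(traj_json, fh, indent=2, sort_keys=True)
        artifacts.append(out / "trajectory_fit.json")

        stage = _stage("survival")
        table2_frames = []
        for outcome, pheno in (("htn", "fbs"), ("t2d", "sbp")):
            if pheno not in assignments:
                continue
            rep = table2_report(
                panel_qc, assignments[pheno], wgrs[pheno], outcome,
                grouping_phenotype=pheno,
                entry_at_second_visit=config.entry_at_second_visit)
            inc = rep.incidence_rows.assign(section="incidence")
            cox = rep.cox_rows.assign(section="cox")
            frame = pd.concat([inc, cox], ignore_index=True)
            frame.insert(0, "outcome", outcome)
            frame.insert(1, "grouping", pheno)
            table2_frames.append(frame)
            counts[f"survival_{outcome}"] = rep.exclusion_report
        pd.concat(table2_frames, ignore_index=True).to_csv(
            out / "table2.tsv", sep="\t", index=False)
        artifacts.append(out / "table2.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": rng_seed,
        "config": config.to_dict(),
        "stage_counts": counts,
        "artifacts": {str(p.relative_to(out)): _sha256(p)
                      for p in sorted(set(artifacts))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return out
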