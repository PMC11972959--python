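"""The cohort container and its on-disk text formats.

A :class:`CohortPanel` is the single object every analysis stage consumes:
additive genotype dosages with missingness, per-subject baseline covariates,
long-format biennial visits, latent trajectory labels, and event times.
Storage is a directory of TSV files plus a JSON manifest; genotypes can
additionally be exported to / imported from a minimal GT-based VCF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASELINE_COLUMNS = [
    "subject_id", "age", "sex", "bmi", "smoking", "alcohol", "exercise",
    "med_antidiabetic", "med_antihypertensive",
    "prevalent_t2d", "prevalent_htn", "prevalent_stroke",
]

VISIT_COLUMNS = ["subject_id", "visit", "time_years", "fbs", "sbp"]

EVENT_COLUMNS = ["subject_id", "t2d_time", "t2d_event", "htn_time", "htn_event"]


class CohortParseError(ValueError):
    """Raised when a cohort file on disk is malformed; names file and line."""


@dataclass
class CohortPanel:
    """Per-subject genotypes, covariates, visits and events.

    genotypes: float array [n_subjects, n_snps] with entries {0,1,2} or NaN.
    variant_meta: one row per SNP (snp_id, chrom, pos, effect_allele,
        other_allele, true_maf, ...); ``pos`` is 1-based.
    visits: long format (subject_id, visit, time_years, fbs, sbp).
    """

    subject_ids: list[str]
    genotypes: np.ndarray
    variant_meta: pd.DataFrame
    baseline: pd.DataFrame
    visits: pd.DataFrame
    true_labels: np.ndarray | None = None
    events: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    # -- basic accessors ----------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.variant_meta["snp_id"])

    def snp_index(self, snp_id: str) -> int:
        ids = self.variant_meta["snp_id"].tolist()
        try:
            return ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def baseline_phenotypes(self) -> pd.DataFrame:
        """Visit-0 FBS/SBP, indexed like ``subject_ids``."""
        v0 = self.visits[self.visits["visit"] == 0].set_index("subject_id")
        v0 = v0.reindex(self.subject_ids)
        return v0[["fbs", "sbp"]].reset_index()

    def subset_subjects(self, keep: np.ndarray | list) -> "CohortPanel":
        keep_idx = np.asarray(keep)
        if keep_idx.dtype == bool:
            keep_idx = np.flatnonzero(keep_idx)
        ids = [self.subject_ids[i] for i in keep_idx]
        id_set = set(ids)
        return CohortPanel(
            subject_ids=ids,
            genotypes=self.genotypes[keep_idx],
            variant_meta=self.variant_meta.copy(),
            baseline=self.baseline[self.baseline.subject_id.isin(id_set)]
            .reset_index(drop=True),
            visits=self.visits[self.visits.subject_id.isin(id_set)]
            .reset_index(drop=True),
            true_labels=None if self.true_labels is None
            else self.true_labels[keep_idx],
            events=None if self.events is None
            else self.events[self.events.subject_id.isin(id_set)]
            .reset_index(drop=True),
            meta=dict(self.meta),
        )

    # -- equality (used by the round-trip contract) -------------------

    def equals(self, other: "CohortPanel") -> bool:
        if self.subject_ids != other.subject_ids:
            return False
        if not np.array_equal(self.genotypes, other.genotypes, equal_nan=True):
            return False
        for a, b in ((self.variant_meta, other.variant_meta),
                     (self.baseline, other.baseline),
                     (self.visits, other.visits),
                     (self.events, other.events)):
            if (a is None) != (b is None):
                return False
            if a is not None and not a.reset_index(drop=True).equals(
                    b.reset_index(drop=True)):
                return False
        if (self.true_labels is None) != (other.true_labels is None):
            return False
        if self.true_labels is not None and not np.array_equal(
                self.true_labels, other.true_labels):
            return False
        return True


# ---------------------------------------------------------------------
# directory round-trip
# ---------------------------------------------------------------------

def write_cohort(panel: CohortPanel, directory: str | Path) -> list[Path]:
    """Write a panel as a directory of TSV files + manifest; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    geno = pd.DataFrame(panel.genotypes, columns=panel.snp_ids)
    geno.insert(0, "subject_id", panel.subject_ids)
    p = directory / "genotypes.tsv"
    # dosages are small integers; write them as such, NaN as NA
    with open(p, "w") as fh:
        fh.write("\t".join(geno.columns) + "\n")
        for i in range(len(geno)):
            row = [str(geno.iat[i, 0])]
            for v in panel.genotypes[i]:
                row.append("NA" if np.isnan(v) else str(int(v)))
            fh.write("\t".join(row) + "\n")
    written.append(p)

    for name, df in (("variants", panel.variant_meta),
                     ("baseline", panel.baseline),
                     ("visits", panel.visits),
                     ("events", panel.events)):
        if df is None:
            continue
        p = directory / f"{name}.tsv"
        # %.17g is round-trippable for float64
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

    if panel.true_labels is not None:
        p = directory / "true_labels.tsv"
        pd.DataFrame({"subject_id": panel.subject_ids,
                      "traj_group": panel.true_labels}).to_csv(
            p, sep="\t", index=False)
        written.append(p)

    p = directory / "panel.json"
    with open(p, "w") as fh:
        json.dump({"n_subjects": panel.n_subjects, "n_snps": panel.n_snps,
                   "meta": panel.meta}, fh, indent=2, sort_keys=True)
    written.append(p)
    return written


def _read_tsv(path: Path, required: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line
        raise CohortParseError(f"{path.name}: {exc}") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortParseError(
                f"{path.name}: line 1: missing columns {missing}")
    return df


def read_cohort(directory: str | Path) -> CohortPanel:
    """Read a panel written by :func:`write_cohort` (field-for-field)."""
    directory = Path(directory)
    gpath = directory / "genotypes.tsv"
    if not gpath.exists():
        raise CohortParseError(f"{gpath.name}: file not found in {directory}")
    with open(gpath) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "subject_id":
            raise CohortParseError(
                f"{gpath.name}: line 1: first column must be subject_id")
        snp_ids = header[1:]
        subject_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise CohortParseError(
                    f"{gpath.name}: line {lineno}: expected "
                    f"{len(header)} fields, found {len(parts)}")
            subject_ids.append(parts[0])
            try:
                rows.append(np.array(
                    [np.nan if v == "NA" else float(v) for v in parts[1:]]))
            except ValueError as exc:
                raise CohortParseError(
                    f"{gpath.name}: line {lineno}: {exc}") from exc
    genotypes = (np.vstack(rows) if rows
                 else np.empty((0, len(snp_ids))))
    bad = genotypes[~np.isnan(genotypes)]
    if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
        raise CohortParseError(
            f"{gpath.name}: dosages must be 0, 1, 2 or NA")

    variant_meta = _read_tsv(directory / "variants.tsv", ["snp_id"])
    if list(variant_meta["snp_id"]) != snp_ids:
        raise CohortParseError(
            "variants.tsv: SNP order disagrees with genotypes.tsv header")
    baseline = _read_tsv(directory / "baseline.tsv", ["subject_id"])
    visits = _read_tsv(directory / "visits.tsv", VISIT_COLUMNS)
    # integral times serialize without a decimal point; restore the dtype
    visits["time_years"] = visits["time_years"].astype(float)
    events = None
    if (directory / "events.tsv").exists():
        events = _read_tsv(directory / "events.tsv", ["subject_id"])
    labels = None
    if (directory / "true_labels.tsv").exists():
        ldf = _read_tsv(directory / "true_labels.tsv",
                        ["subject_id", "traj_group"])
        labels = ldf["traj_group"].to_numpy()
    meta = {}
    if (directory / "panel.json").exists():
        with open(directory / "panel.json") as fh:
            meta = json.load(fh).get("meta", {})
    return CohortPanel(subject_ids=subject_ids, genotypes=genotypes,
                       variant_meta=variant_meta, baseline=baseline,
                       visits=visits, true_labels=labels, events=events,
                       meta=meta)


# ---------------------------------------------------------------------
# VCF export / import (GT-coded; dosage counts the ALT = effect allele)
# ---------------------------------------------------------------------

_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def export_vcf(panel: CohortPanel, path: str | Path) -> Path:
    """Write genotypes as an uncompressed VCFv4.2 with GT fields.

    Dosage 0/1/2 maps to 0/0, 0/1, 1/1; a missing call is ``./.``. The
    effect allele is the ALT allele, so the ALT dosage equals the stored
    additive dosage.
    """
    path = Path(path)
    vm = panel.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(vm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.subject_ids) + "\n")
        for j, row in enumerate(vm.itertuples(index=False)):
            gts = []
            for d in panel.genotypes[:, j]:
                gts.append("./." if np.isnan(d) else _GT_BY_DOSAGE[int(d)])
            fh.write("\t".join([
                str(row.chrom), str(int(row.pos)), str(row.snp_id),
                str(row.other_allele), str(row.effect_allele),
                ".", "PASS", ".", "GT", *gts]) + "\n")
    return path


def genotypes_from_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a GT-based VCF into (dosages, variant table, sample ids).

    Dosage counts the ALT allele; ``./.`` becomes NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        meta.append({"snp_id": var.ID, "chrom": var.CHROM, "pos": var.POS,
                     "effect_allele": var.ALT[0] if var.ALT else ".",
                     "other_allele": var.REF})
    dosages = (np.vstack(rows).T if rows
               else np.empty((len(samples), 0)))
    return dosages, pd.DataFrame(meta), samples
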