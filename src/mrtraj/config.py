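"""Configuration objects for the synthetic cohort and the pipeline.

The simulation defaults emulate a Korean middle-aged biennial cohort:
~8,500 genotyped subjects aged 40-69, 91 fasting-blood-sugar (FBS) and 68
systolic-blood-pressure (SBP) instrument variants with a single shared
large-effect variant, eight biennial visits, two latent trajectory classes
(one with a reverse-U-shaped course), and incident type-2-diabetes /
hypertension event times censored administratively after 16 years.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

#: mg/dL per mmol/L of glucose; FBS is simulated in mmol/L but several
#: reports in the field print mg/dL.
MGDL_PER_MMOLL = 18.016


def _as_tuple(x) -> tuple:
    return tuple(x) if isinstance(x, (list, tuple)) else (x,)


@dataclass
class EventModel:
    """Proportional-hazards generator for incident T2D and hypertension.

    ``baseline_hazard`` is the per-year hazard for a reference subject;
    ``log_hr`` maps covariate names to log hazard ratios. Supported
    covariate keys: ``uncontrolled`` (latent trajectory class indicator),
    ``age`` (per year, centered at 55), ``male``, ``bmi`` (per kg/m^2,
    centered at 24.5). ``shape`` is the Weibull shape (1 = exponential).
    """

    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {"t2d": 0.075, "htn": 0.125}
    )
    log_hr: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "t2d": {"uncontrolled": math.log(1.25), "age": 0.03,
                    "male": 0.20, "bmi": 0.05},
            "htn": {"uncontrolled": math.log(1.30), "age": 0.04,
                    "male": 0.15, "bmi": 0.08},
        }
    )
    shape: float = 1.0

    def validate(self) -> None:
        for k, h in self.baseline_hazard.items():
            if h <= 0:
                raise ValueError(f"baseline hazard for {k!r} must be > 0")
        if self.shape <= 0:
            raise ValueError("Weibull shape must be > 0")


#: default latent-class mean curves (intercept, linear, quadratic, cubic),
#: phenotype units vs. years from baseline; the second class of each
#: phenotype rises then falls (reverse U-shape) and sits at a higher level.
DEFAULT_TRAJ_COEFFICIENTS: dict[str, list[list[float]]] = {
    "fbs": [[0.0, 0.02, 0.0, 0.0], [0.6, 0.18, -0.013, 0.0]],
    "sbp": [[0.0, 0.30, 0.0, 0.0], [8.0, 3.00, -0.250, 0.0]],
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Genotypes are drawn in Hardy-Weinberg proportions, baseline FBS (mmol/L)
    and SBP (mmHg) follow a bidirectional linear structural model with a
    shared latent confounder, visit-level phenotypes add a latent-class
    polynomial in time, and event times follow proportional hazards.
    """

    n_subjects: int = 8500
    n_snps_fbs: int = 91
    n_snps_sbp: int = 68
    n_shared: int = 1
    n_snps_null: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    # per-allele effect-size SDs (phenotype units per effect allele)
    beta_scale_x: float = 0.05   # FBS, mmol/L
    beta_scale_y: float = 1.5    # SBP, mmHg
    shared_effect_multiplier: float = 3.0
    # structural causal effects
    causal_fbs_to_sbp: float = 3.26    # mmHg per mmol/L (1.63 per 0.5 mmol/L)
    causal_sbp_to_fbs: float = 0.063   # mmol/L per mmHg (0.63 per 10 mmHg)
    # horizontal pleiotropy of instrument SNPs on the opposite phenotype
    pleiotropy_mode: str = "none"      # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    # unitless latent confounder and its loadings on each phenotype
    confounder_sd: float = 1.0
    confounder_loading_fbs: float = 0.15   # mmol/L per unit U
    confounder_loading_sbp: float = 4.0    # mmHg per unit U
    # phenotype location/noise
    fbs_mean: float = 4.9
    sbp_mean: float = 117.4
    fbs_noise_sd: float = 0.30
    sbp_noise_sd: float = 12.0
    age_effect_fbs: float = 0.005  # mmol/L per year of age
    age_effect_sbp: float = 0.30   # mmHg per year of age
    # longitudinal design
    n_visits: int = 8
    visit_spacing_years: float = 2.0
    visit_noise_sd_fbs: float = 0.30
    visit_noise_sd_sbp: float = 8.0
    visit_missing_rate: float = 0.0
    traj_group_shares: tuple[float, ...] = (0.8, 0.2)
    traj_coefficients: dict[str, list[list[float]]] = field(
        default_factory=lambda: {k: [row[:] for row in v]
                                 for k, v in DEFAULT_TRAJ_COEFFICIENTS.items()}
    )
    # events and baseline disease history
    event_model: EventModel = field(default_factory=EventModel)
    # fraction (float) or exact planted count (int) of prevalent cases
    prevalence: dict[str, float | int] = field(
        default_factory=lambda: {"t2d": 892 / 8510, "htn": 1293 / 8510,
                                 "stroke": 34 / 8510}
    )
    missing_rate: float = 0.01
    censor_date_years: float = 16.0
    seed: int = 0

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_snps_fbs": self.n_snps_fbs,
            "n_snps_sbp": self.n_snps_sbp,
            "n_visits": self.n_visits,
        }
        for name, v in counts.items():
            if not isinstance(v, (int,)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_shared < 0 or self.n_snps_null < 0:
            raise ValueError("n_shared and n_snps_null must be >= 0")
        if self.n_shared > min(self.n_snps_fbs, self.n_snps_sbp):
            raise ValueError("n_shared cannot exceed min(n_snps_fbs, n_snps_sbp)")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        shares = tuple(self.traj_group_shares)
        if abs(sum(shares) - 1.0) > 1e-12:
            raise ValueError("traj_group_shares must sum to 1 within 1e-12")
        if any(s <= 0 for s in shares):
            raise ValueError("traj_group_shares must be strictly positive")
        for pheno in ("fbs", "sbp"):
            coefs = self.traj_coefficients.get(pheno)
            if coefs is None or len(coefs) != len(shares):
                raise ValueError(
                    f"traj_coefficients[{pheno!r}] must give one row of "
                    f"(intercept, linear, quadratic, cubic) per group"
                )
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy_mode must be none|balanced|directional")
        for rate_name in ("missing_rate", "visit_missing_rate"):
            r = getattr(self, rate_name)
            if not 0 <= r < 1:
                raise ValueError(f"{rate_name} must be in [0, 1)")
        if abs(self.causal_fbs_to_sbp * self.causal_sbp_to_fbs) >= 1:
            raise ValueError(
                "structural system is singular: |causal_fbs_to_sbp * "
                "causal_sbp_to_fbs| >= 1"
            )
        if self.visit_spacing_years <= 0 or self.censor_date_years <= 0:
            raise ValueError("visit spacing and censoring horizon must be > 0")
        self.event_model.validate()

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["traj_group_shares"] = list(self.traj_group_shares)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "traj_group_shares" in d:
            d["traj_group_shares"] = tuple(d["traj_group_shares"])
        if "event_model" in d and isinstance(d["event_model"], Mapping):
            d["event_model"] = EventModel(**d["event_model"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: simulation + per-stage options."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # instrument selection
    qc_call_rate: float = 0.96
    qc_hwe_p: float = 1e-4
    qc_maf: float = 0.01
    qc_subject_missing: float = 0.05
    gwas_covariates: tuple[str, ...] = ("age", "sex")
    clump_r2: float = 0.01
    clump_window_bp: int = 1_000_000
    clump_p: float = 5e-8
    # mr
    mr_n_boot: int = 1000
    mr_exclude_shared: bool = True
    # trajectory
    traj_phenotypes: tuple[str, ...] = ("fbs", "sbp")
    traj_k_range: tuple[int, ...] = (1, 2, 3)
    traj_orders: tuple[int, ...] = (2,)
    traj_restarts: int = 5
    # survival
    survival_outcomes: tuple[str, ...] = ("t2d", "htn")
    entry_at_second_visit: bool = False
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if not self.traj_k_range:
            raise ValueError("traj_k_range must be nonempty")
        if self.clump_r2 <= 0 or self.clump_window_bp <= 0:
            raise ValueError("clump thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.pop("sim", {}))
        tuple_fields = {"gwas_covariates", "traj_phenotypes", "traj_k_range",
                        "traj_orders", "survival_outcomes"}
        kwargs: dict[str, Any] = {}
        for k, v in raw.items():
            kwargs[k] = tuple(v) if k in tuple_fields and isinstance(
                v, Sequence) and not isinstance(v, str) else v
        cfg = cls(sim=sim, **kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        for k in ("gwas_covariates", "traj_phenotypes", "traj_k_range",
                  "traj_orders", "survival_outcomes"):
            d[k] = list(d[k])
        return d
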