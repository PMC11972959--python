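import numpy as np
import pandas as pd
import pytest

from mrtraj import CohortPanel, SimulationConfig, generate_cohort


def tiny_config(**overrides) -> SimulationConfig:
    base = dict(n_subjects=300, n_snps_fbs=12, n_snps_sbp=10, n_shared=1,
                missing_rate=0.02, seed=42)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_panel() -> CohortPanel:
    """A small cohort shared by read-only tests."""
    return generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def midsize_panel() -> CohortPanel:
    """A cohort big enough for stable regression-based checks."""
    return generate_cohort(tiny_config(n_subjects=2500, missing_rate=0.0,
                                       seed=7))


def manual_panel(genotypes, mafs=None, **kw):
    """Build a panel directly from a dosage matrix for worked fixtures."""
    genotypes = np.asarray(genotypes, dtype=float)
    n, m = genotypes.shape
    subject_ids = [f"S{i:03d}" for i in range(n)]
    variant_meta = pd.DataFrame({
        "snp_id": [f"rs{j}" for j in range(m)],
        "chrom": kw.get("chrom", [1] * m),
        "pos": kw.get("pos", [1000 * (j + 1) for j in range(m)]),
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
        "true_maf": mafs if mafs is not None else [0.3] * m,
    })
    baseline = pd.DataFrame({
        "subject_id": subject_ids,
        "age": kw.get("age", np.full(n, 55.0)),
        "sex": kw.get("sex", ["male" if i % 2 else "female"
                              for i in range(n)]),
        "bmi": np.full(n, 24.0),
        "smoking": ["never"] * n, "alcohol": ["no"] * n,
        "exercise": ["no"] * n,
        "med_antidiabetic": 0, "med_antihypertensive": 0,
        "prevalent_t2d": 0, "prevalent_htn": 0, "prevalent_stroke": 0,
    })
    fbs = np.asarray(kw.get("fbs", np.zeros(n)), dtype=float)
    sbp = np.asarray(kw.get("sbp", np.zeros(n)), dtype=float)
    visits = pd.DataFrame({
        "subject_id": subject_ids * 2,
        "visit": [0] * n + [1] * n,
        "time_years": [0.0] * n + [2.0] * n,
        "fbs": np.concatenate([fbs, fbs]),
        "sbp": np.concatenate([sbp, sbp]),
    }).sort_values(["subject_id", "visit"], kind="mergesort",
                   ignore_index=True)
    return CohortPanel(subject_ids=subject_ids, genotypes=genotypes,
                       variant_meta=variant_meta, baseline=baseline,
                       visits=visits)
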