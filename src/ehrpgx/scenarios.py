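"""Packaged end-to-end scenarios wiring generator -> QC -> phenotypes -> GWAS.

A :class:`Scenario` is fully self-describing: the scenario plus a master
seed reproduces every output.  Two scenarios ship with the package:

* ``statin_like`` — a lipid-lowering cohort with two causal panel variants
  (one with both baseline and PGx effects, one purely pharmacogenetic)
  among null variants, multiplicative drug action on a log-scale biomarker.
* ``null`` — no genetic effects anywhere, for type-I error calibration.

The replication-counting demo applies the thresholding utilities to the
bundled summary statistics of seven published lipid-statin loci
(discovery/replication betas and replication p-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import (
    DrugResponseGWAS,
    bonferroni_threshold,
    count_below,
    directional_concordance,
)
from .cohort import ScenarioConfig, qc_cascade
from .generate import (
    GenerativeParams,
    RxBehavior,
    VariantSpec,
    VisitSchedule,
    simulate_ehr,
)
from .io import QCAudit, default_code_map
from .phenotypes import build_covariates, derive_phenotypes

__all__ = [
    "TABLE1_FIXTURE",
    "Scenario",
    "ScenarioResult",
    "null_scenario",
    "replication_count_demo",
    "run_scenario",
    "statin_like_scenario",
]

# Published discovery/replication summary statistics for seven lipid-statin
# response loci (per-locus discovery beta, replication beta, replication p).
TABLE1_FIXTURE = pd.DataFrame(
    [
        ("rs6511720", "LDLR", "absolute", -0.103, 0.023, 0.30),
        ("rs10455872", "SLC22A3_LPA", "log_relative", -0.148, -0.078, 9.35e-03),
        ("rs7412_ldl", "APOE", "log_relative", 0.254, 0.205, 4.01e-14),
        ("rs77265569", "LDLR", "absolute", -0.085, -0.002, 0.95),
        ("rs118039278", "SLC22A3_LPA", "log_relative", -0.122, -0.070, 4.98e-02),
        ("rs7803925", "ZNF800", "log_relative", -0.078, -0.019, 0.49),
        ("rs7412_tc", "APOE", "log_relative", 0.169, 0.129, 1.15e-04),
    ],
    columns=["variant_id", "locus", "mode", "beta_discovery", "beta_replication", "p_replication"],
)


@dataclass
class Scenario:
    """Self-describing end-to-end run definition."""

    name: str
    n: int
    params: GenerativeParams
    behavior: RxBehavior
    schedule: VisitSchedule
    scenario_config: ScenarioConfig
    biomarker: str = "LDL"
    primary: str = "statin"
    model_variants: tuple[str, ...] = ("unadjusted", "baseline_adjusted")
    modes: tuple[str, ...] = ("absolute", "log_relative")
    causal_variants: tuple[str, ...] = ()


@dataclass
class ScenarioResult:
    """Bundle of every stage output plus a summary against expectations."""

    scenario: Scenario
    seed: int
    measures: pd.DataFrame
    prescriptions: pd.DataFrame
    cohort: pd.DataFrame
    audit: QCAudit
    phenotypes: pd.DataFrame
    associations: pd.DataFrame
    summary: dict
    failed_stage: str | None = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None


def statin_like_scenario(n: int = 4000) -> Scenario:
    """Lipid-response scenario: 20-variant panel, 2 causal, log-scale drug."""
    variants = []
    for j in range(20):
        maf = 0.1 + 0.02 * j
        if j == 3:
            variants.append(VariantSpec(f"v{j:02d}", maf, beta0=0.10, gammaD=0.08))
        elif j == 11:
            variants.append(VariantSpec(f"v{j:02d}", maf, beta0=0.0, gammaD=0.08))
        else:
            variants.append(VariantSpec(f"v{j:02d}", maf))
    params = GenerativeParams(
        scale="log",
        intercept=float(np.log(4.5)),
        betaD=-0.35,
        betaE=1.0,
        var_env_persistent=0.02,
        var_env_occasion=0.02,
        variants=variants,
        sex_effect=-0.02,
        age_effect=0.002,
    )
    behavior = RxBehavior(p_same_class_comed=0.05, p_combo=0.03, p_switch=0.05)
    return Scenario(
        name="statin_like",
        n=n,
        params=params,
        behavior=behavior,
        schedule=VisitSchedule(),
        scenario_config=ScenarioConfig(mode="lenient", measure_mode="average", min_baseline={"LDL": 2.0}),
        causal_variants=("v03", "v11"),
    )


def null_scenario(n: int = 2000, n_variants: int = 50) -> Scenario:
    """No genetic effects anywhere: calibration of the type-I error."""
    variants = [VariantSpec(f"n{j:03d}", 0.1 + 0.3 * (j % 7) / 7) for j in range(n_variants)]
    params = GenerativeParams(
        scale="natural",
        intercept=4.5,
        betaD=-1.2,
        var_env_persistent=0.25,
        var_env_occasion=0.25,
        variants=variants,
    )
    return Scenario(
        name="null",
        n=n,
        params=params,
        behavior=RxBehavior(),
        schedule=VisitSchedule(),
        scenario_config=ScenarioConfig(mode="lenient", measure_mode="average", min_baseline={}),
        causal_variants=(),
    )


def run_scenario(scenario: Scenario, seed: int) -> ScenarioResult:
    """Execute every stage; a stage failure marks the bundle, not an exception."""
    code_map = default_code_map()
    stage = "simulate"
    try:
        measures, rx, pop, _truth = simulate_ehr(
            scenario.n,
            scenario.params,
            scenario.behavior,
            scenario.schedule,
            seed,
            code_map,
            biomarker=scenario.biomarker,
        )
        stage = "emulate"
        cohort, audit = qc_cascade(
            measures,
            rx,
            code_map,
            scenario.scenario_config,
            scenario.biomarker,
            scenario.primary,
            persons=pop.persons,
        )
        stage = "derive"
        covariates = build_covariates(cohort, seed=seed + 1)
        phenotypes = derive_phenotypes(cohort, covariates)
        stage = "assoc"
        dosages = pop.dosage_frame()
        model = DrugResponseGWAS(
            cohort,
            dosages,
            covariates,
            model_variants=scenario.model_variants,
            modes=scenario.modes,
        )
        results = model.fit()
        stage = "summarize"
        table = results.table
        m = table["variant_id"].nunique()
        thr = bonferroni_threshold(0.05, m)
        unadj = table[(table["model"] == "unadjusted") & (table["flag"] == "")]
        hits = set(unadj.loc[unadj["p"] < thr, "variant_id"])
        summary = {
            "cohort_n": len(cohort),
            "audit_conserved": audit.conserved(),
            "bonferroni_threshold": thr,
            "significant_unadjusted": sorted(hits),
            "expected_causal": sorted(scenario.causal_variants),
            "causal_recovered": sorted(hits & set(scenario.causal_variants)),
            "false_positives": sorted(hits - set(scenario.causal_variants)),
        }
    except Exception as exc:  # bundle marked failed with the failing stage
        return ScenarioResult(
            scenario, seed,
            measures=pd.DataFrame(), prescriptions=pd.DataFrame(),
            cohort=pd.DataFrame(), audit=QCAudit([], {}, {}, 0, 0),
            phenotypes=pd.DataFrame(), associations=pd.DataFrame(),
            summary={"error": f"{type(exc).__name__}: {exc}"},
            failed_stage=stage,
        )
    return ScenarioResult(scenario, seed, measures, rx, cohort, audit, phenotypes, table, summary)


def replication_count_demo(alpha: float = 0.05) -> dict:
    """Replication counting over the bundled seven-locus summary statistics."""
    t = TABLE1_FIXTURE
    thr = bonferroni_threshold(alpha, len(t))
    p = t["p_replication"].to_numpy()
    nominal_mask = p < alpha
    return {
        "m": len(t),
        "bonferroni_threshold": thr,
        "n_replicated_bonferroni": count_below(p, thr),
        "n_replicated_nominal": count_below(p, alpha),
        "n_directionally_concordant": directional_concordance(
            t["beta_discovery"], t["beta_replication"], nominal_mask
        ),
    }
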