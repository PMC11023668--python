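"""Synthetic longitudinal-EHR generator.

Generates populations with genotypes, environments, prescription streams and
biomarker trajectories under the longitudinal phenotype model

    Y_t = intercept + beta0·G + betaE·E + gammaE·G·E + D_t·(betaD + gammaD·G) + eps_t

where ``E`` is a persistent per-person environment draw shared by all of that
person's measures and ``eps_t`` is i.i.d. occasion noise.  The drug indicator
``D_t`` switches on at the first primary-medication prescription and stays on.
On the log scale the same linear predictor applies to ``log Y``, so the drug
acts multiplicatively on the biomarker.

The generator's defaults define the study conditions of the packaged
scenarios; they are not tuned per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CodeMap, default_code_map

__all__ = [
    "GenerativeParams",
    "PRSArchitecture",
    "Population",
    "RxBehavior",
    "VariantSpec",
    "VisitSchedule",
    "simulate_controls",
    "simulate_ehr",
    "simulate_population",
    "simulate_prescriptions",
    "simulate_response_cohort",
    "simulate_trajectory",
    "substream",
]


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG substream derived from the master seed and a stage name.

    Lets any stage be rerun in isolation with reproducible draws.
    """
    h = np.frombuffer(stage.encode(), dtype=np.uint8).astype(np.uint64)
    stage_key = int(h.sum() * 1009 + len(stage)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), stage_key]))


@dataclass(frozen=True)
class VariantSpec:
    """One panel variant: allele frequency, baseline effect, PGx effect."""

    variant_id: str
    maf: float
    beta0: float = 0.0
    gammaD: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if not (np.isfinite(self.beta0) and np.isfinite(self.gammaD)):
            raise ValueError("variant effects must be finite")


@dataclass(frozen=True)
class PRSArchitecture:
    """Many-small-effect polygenic background contributing to baseline.

    ``var_baseline`` is the variance the (standardized) true score contributes
    to the baseline linear predictor; per-variant weights are drawn normal.
    """

    n_variants: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5
    var_baseline: float = 0.25


@dataclass
class GenerativeParams:
    """Parameters of the longitudinal biomarker model.

    ``scale`` selects whether the linear predictor is the biomarker itself
    (``natural``) or its natural log (``log``, multiplicative drug action).
    ``var_env_persistent`` is Var(E) of the shared environment, entering the
    trajectory through ``betaE``; ``var_env_occasion`` is Var(eps_t) directly.
    """

    scale: str = "natural"
    intercept: float = 4.0
    betaD: float = -1.0
    betaE: float = 1.0
    gammaE: float = 0.0
    var_env_persistent: float = 0.25
    var_env_occasion: float = 0.25
    variants: list[VariantSpec] = field(default_factory=list)
    prs_arch: PRSArchitecture | None = None
    prs_gammaD: float = 0.0
    sex_effect: float = 0.0
    age_effect: float = 0.0

    def __post_init__(self):
        if self.scale not in ("natural", "log"):
            raise ValueError("scale must be 'natural' or 'log'")
        if self.var_env_persistent < 0 or self.var_env_occasion < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class RxBehavior:
    """Prescription-stream behaviour knobs the QC cascade later filters on."""

    mean_interval_days: int = 61
    regularity: float = 0.9
    p_same_class_comed: float = 0.0
    p_addon: float = 0.0
    p_combo: float = 0.0
    p_switch: float = 0.0
    drug_menu: dict[str, list[float]] = field(
        default_factory=lambda: {"STA1": [20, 40, 80], "STA2": [10, 20, 40]}
    )
    comed_code: str = "EZE1"
    addon_code: str = "SUL1"
    combo_code: str = "CMB1"

    def __post_init__(self):
        for p in (self.regularity, self.p_same_class_comed, self.p_addon, self.p_combo, self.p_switch):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_interval_days <= 0:
            raise ValueError("interval must be positive")


@dataclass
class VisitSchedule:
    """Measurement and treatment timing of the simulated clinic."""

    rate_pre_per_year: float = 1.8
    rate_post_per_year: float = 1.8
    start_low: int = 900
    start_high: int = 1400
    horizon_post_days: int = 1095
    control_spacing: tuple[int, int] = (183, 1095)

    def __post_init__(self):
        if self.rate_pre_per_year < 0 or self.rate_post_per_year < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class Population:
    """Per-person latent state: genotypes, environment, optional true PRS."""

    persons: pd.DataFrame  # person_id, sex, age0
    genotypes: np.ndarray  # n x m dosages in {0,1,2}
    variant_ids: list[str]
    env: np.ndarray  # persistent environment draw per person
    prs: np.ndarray | None = None  # standardized true score
    prs_genotypes: np.ndarray | None = None
    prs_weights: pd.DataFrame | None = None  # variant_id, effect_allele, weight

    @property
    def n(self) -> int:
        return len(self.persons)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes,
            index=pd.Index(self.persons["person_id"], name="person_id"),
            columns=self.variant_ids,
            dtype=float,
        )


def simulate_population(n: int, params: GenerativeParams, seed: int) -> Population:
    """Draw the latent per-person state.

    Genotypes are binomial(2, maf) per variant (Hardy-Weinberg); sex is
    balanced; age at epoch uniform on [40, 70); the persistent environment is
    N(0, var_env_persistent).  With a PRS architecture, background genotypes
    and normal weights are drawn and the true score standardized in-sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "population")
    ids = [f"P{i:06d}" for i in range(n)]
    sex = rng.integers(0, 2, size=n)
    age0 = rng.uniform(40, 70, size=n)
    mafs = np.array([v.maf for v in params.variants])
    genotypes = (
        rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
        if len(mafs)
        else np.zeros((n, 0))
    )
    env = rng.normal(0.0, np.sqrt(params.var_env_persistent), size=n)

    prs = prs_gt = prs_w = None
    if params.prs_arch is not None:
        arch = params.prs_arch
        bg_maf = rng.uniform(arch.maf_low, arch.maf_high, size=arch.n_variants)
        prs_gt = rng.binomial(2, bg_maf, size=(n, arch.n_variants)).astype(float)
        w = rng.normal(0.0, 1.0, size=arch.n_variants)
        raw = prs_gt @ w
        sd = raw.std()
        if sd == 0:
            raise ValueError("degenerate PRS architecture: zero-variance score")
        prs = (raw - raw.mean()) / sd
        prs_w = pd.DataFrame(
            {
                "variant_id": [f"bg{j:04d}" for j in range(arch.n_variants)],
                "effect_allele": "A",
                "weight": w,
            }
        )
    persons = pd.DataFrame({"person_id": ids, "sex": sex, "age0": age0})
    return Population(persons, genotypes, [v.variant_id for v in params.variants], env, prs, prs_gt, prs_w)


def _linear_predictor(pop: Population, params: GenerativeParams, idx: np.ndarray, treated: np.ndarray) -> np.ndarray:
    """Noise-free part of the model for persons ``idx`` at drug status ``treated``."""
    g = pop.genotypes[idx]
    beta0 = np.array([v.beta0 for v in params.variants])
    gammaD = np.array([v.gammaD for v in params.variants])
    lin = np.full(len(idx), params.intercept, dtype=float)
    if g.shape[1]:
        lin += g @ beta0
    env = pop.env[idx]
    lin += params.betaE * env
    if params.gammaE != 0.0 and g.shape[1]:
        lin += params.gammaE * g[:, 0] * env  # interaction acts through the first panel variant
    lin += params.sex_effect * pop.persons["sex"].to_numpy()[idx]
    lin += params.age_effect * pop.persons["age0"].to_numpy()[idx]
    if pop.prs is not None and params.prs_arch is not None:
        lin += np.sqrt(params.prs_arch.var_baseline) * pop.prs[idx]
    drug = params.betaD + (g @ gammaD if g.shape[1] else 0.0)
    if pop.prs is not None and params.prs_gammaD != 0.0:
        drug = drug + params.prs_gammaD * pop.prs[idx]
    lin += np.asarray(treated, dtype=float) * drug
    return lin


def simulate_trajectory(
    pop: Population,
    person_index: int,
    params: GenerativeParams,
    times: np.ndarray,
    start_day: int | None,
    rng: np.random.Generator,
    biomarker: str = "LDL",
    unit: str = "mmol_L",
) -> pd.DataFrame:
    """Biomarker measures for one person at the given days.

    ``start_day=None`` means drug-naive (D_t = 0 throughout); otherwise
    D_t = 1 for t >= start_day.
    """
    times = np.asarray(times, dtype=int)
    treated = np.zeros(len(times)) if start_day is None else (times >= start_day).astype(float)
    idx = np.full(len(times), person_index)
    lin = _linear_predictor(pop, params, idx, treated)
    lin += rng.normal(0.0, np.sqrt(params.var_env_occasion), size=len(times))
    values = np.exp(lin) if params.scale == "log" else lin
    return pd.DataFrame(
        {
            "person_id": pop.persons["person_id"].iloc[person_index],
            "date": times,
            "biomarker": biomarker,
            "value": values,
            "unit": unit,
            "source": "ehr",
        }
    )


def simulate_prescriptions(
    person_id: str,
    behavior: RxBehavior,
    code_map: CodeMap,
    start_day: int,
    horizon_days: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Prescription stream for one person starting at ``start_day``.

    Refills are scheduled every ``mean_interval_days`` up to the horizon and
    independently realized with probability ``regularity`` (the first is
    always issued: it defines the start).  Optional events: a same-class
    co-medication within a year of start, a consistently-taken add-on drug,
    combination products, and a drug-type switch between start and horizon.
    """
    rows: list[dict] = []
    codes = list(behavior.drug_menu)
    code = codes[int(rng.integers(len(codes)))]
    dose = float(rng.choice(behavior.drug_menu[code]))
    use_combo = rng.random() < behavior.p_combo
    switch_at = None
    if behavior.p_switch > 0 and rng.random() < behavior.p_switch:
        switch_at = start_day + int(rng.integers(behavior.mean_interval_days, max(horizon_days, behavior.mean_interval_days + 1)))

    scheduled = np.arange(start_day, start_day + horizon_days + 1, behavior.mean_interval_days)
    for i, day in enumerate(scheduled):
        if i > 0 and rng.random() > behavior.regularity:
            continue
        cur = code
        if switch_at is not None and day >= switch_at:
            others = [c for c in codes if c != code] or [code]
            cur = others[0]
        if use_combo:
            cur = behavior.combo_code
        entry = code_map[cur]
        menu = behavior.drug_menu.get(cur)
        d = dose if cur == code else float(rng.choice(menu)) if menu else dose
        rows.append(
            {
                "person_id": person_id,
                "date": int(day),
                "code": cur,
                "description": f"{entry.ingredient.replace('_', ' + ').title()} {d:g}mg tablets",
                "quantity": 28,
            }
        )
    if rng.random() < behavior.p_same_class_comed:
        day = start_day + int(rng.integers(-364, 365))
        entry = code_map[behavior.comed_code]
        rows.append(
            {
                "person_id": person_id,
                "date": max(0, day),
                "code": behavior.comed_code,
                "description": f"{entry.ingredient.title()} 10mg tablets",
                "quantity": 28,
            }
        )
    if rng.random() < behavior.p_addon:
        entry = code_map[behavior.addon_code]
        for day in (start_day - int(rng.integers(30, 360)), start_day + int(rng.integers(30, 360))):
            rows.append(
                {
                    "person_id": person_id,
                    "date": max(0, day),
                    "code": behavior.addon_code,
                    "description": f"{entry.ingredient.title()} 80mg tablets",
                    "quantity": 28,
                }
            )
    return pd.DataFrame(rows, columns=["person_id", "date", "code", "description", "quantity"])


def _poisson_times(rng: np.random.Generator, lo: float, hi: float, rate_per_year: float) -> np.ndarray:
    span = max(0.0, hi - lo)
    k = rng.poisson(rate_per_year * span / 365.25)
    return np.sort(rng.uniform(lo, hi, size=k)).astype(int) if k else np.array([], dtype=int)


def simulate_ehr(
    n: int,
    params: GenerativeParams,
    behavior: RxBehavior,
    schedule: VisitSchedule,
    seed: int,
    code_map: CodeMap | None = None,
    biomarker: str = "LDL",
    unit: str = "mmol_L",
) -> tuple[pd.DataFrame, pd.DataFrame, Population, pd.DataFrame]:
    """Full treated-population EHR: measures, prescriptions, latent state.

    Returns ``(measures, prescriptions, population, truth)`` where ``truth``
    carries the per-variant generative effects for parameter-recovery tests.
    """
    code_map = code_map or default_code_map()
    pop = simulate_population(n, params, seed)
    rng = substream(seed, "ehr")
    measures = []
    rx = []
    for i in range(n):
        pid = pop.persons["person_id"].iloc[i]
        start = int(rng.integers(schedule.start_low, schedule.start_high + 1))
        pre = _poisson_times(rng, 0, start, schedule.rate_pre_per_year)
        post = _poisson_times(rng, start + 1, start + schedule.horizon_post_days, schedule.rate_post_per_year)
        times = np.concatenate([pre, post])
        if len(times):
            measures.append(simulate_trajectory(pop, i, params, times, start, rng, biomarker, unit))
        rx.append(simulate_prescriptions(pid, behavior, code_map, start, schedule.horizon_post_days, rng))
    measures_df = (
        pd.concat(measures, ignore_index=True)
        if measures
        else pd.DataFrame(columns=["person_id", "date", "biomarker", "value", "unit", "source"])
    )
    rx_df = pd.concat(rx, ignore_index=True)
    truth = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in params.variants],
            "maf": [v.maf for v in params.variants],
            "beta0": [v.beta0 for v in params.variants],
            "gammaD": [v.gammaD for v in params.variants],
        }
    )
    return measures_df, rx_df, pop, truth


def simulate_controls(
    n: int,
    params: GenerativeParams,
    schedule: VisitSchedule,
    seed: int,
    biomarker: str = "LDL",
    unit: str = "mmol_L",
) -> tuple[pd.DataFrame, pd.DataFrame, Population]:
    """Drug-naive persons, each with two measures spaced within the allowed band.

    The spacing is uniform over ``schedule.control_spacing`` (the minimum and
    maximum allowed interval between baseline and post-treatment measures);
    prescriptions are empty by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = simulate_population(n, params, seed + 1)
    rng = substream(seed, "controls")
    lo, hi = schedule.control_spacing
    first = rng.integers(0, 365, size=n)
    spacing = rng.integers(lo, hi + 1, size=n)
    frames = []
    for i in range(n):
        times = np.array([first[i], first[i] + spacing[i]])
        frames.append(simulate_trajectory(pop, i, params, times, None, rng, biomarker, unit))
    measures = pd.concat(frames, ignore_index=True)
    empty_rx = pd.DataFrame(columns=["person_id", "date", "code", "description", "quantity"])
    return measures, empty_rx, pop


def simulate_response_cohort(
    n: int,
    params: GenerativeParams,
    seed: int,
    treated: bool = True,
) -> pd.DataFrame:
    """Direct draw of (baseline, post) pairs under the model, skipping the EHR.

    This is the fast path used by the bias/estimand Monte-Carlo studies: one
    baseline measure at D=0 and one post measure at D=``treated``, sharing the
    person's genotype and persistent environment, with independent occasion
    noise.  Columns: person_id, dosage_<variant>, prs, sex, age, baseline, post.
    """
    pop = simulate_population(n, params, seed)
    rng = substream(seed, "cohort")
    idx = np.arange(n)
    lin0 = _linear_predictor(pop, params, idx, np.zeros(n))
    lin1 = _linear_predictor(pop, params, idx, np.full(n, 1.0 if treated else 0.0))
    sd = np.sqrt(params.var_env_occasion)
    lin0 = lin0 + rng.normal(0.0, sd, size=n)
    lin1 = lin1 + rng.normal(0.0, sd, size=n)
    base = np.exp(lin0) if params.scale == "log" else lin0
    post = np.exp(lin1) if params.scale == "log" else lin1
    cols = {
        "person_id": pop.persons["person_id"],
        "sex": pop.persons["sex"],
        "age": pop.persons["age0"],
        "baseline": base,
        "post": post,
    }
    for j, vid in enumerate(pop.variant_ids):
        cols[f"dosage_{vid}"] = pop.genotypes[:, j]
    cols["prs"] = pop.prs if pop.prs is not None else np.zeros(n)
    return pd.DataFrame(cols)
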