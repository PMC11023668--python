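"""Cohort emulation: medication regimens and the drug-response QC cascade.

From raw prescription streams this module reconstructs each person's regimen
(start date, drug type and dose, treatment changes, prescription regularity,
co-medication and add-on status) and applies an ordered cascade of exclusion
rules to produce a drug-response cohort with a full audit.  Stage order:

    comedication, i (baseline & post measures available), ii (prior primary
    care record >= 2 years before start), iii (class prescription after the
    post measure), iv (drug change between start and post measure),
    v (prescription regularity), vi (minimum baseline level),
    drug-group size, cohort size (warning only).

Each excluded person is counted at its first failing stage, so the audit is
conservative: input n = survivors + sum of per-stage removals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CodeMap, QCAudit

__all__ = [
    "QC_STAGES",
    "Regimen",
    "ScenarioConfig",
    "build_regimen",
    "classify_prescriptions",
    "control_pairs",
    "impute_missing_dose",
    "parse_dose",
    "qc_cascade",
    "regularity",
    "select_window_measure",
]

QC_STAGES = [
    "comedication",
    "i_measures",
    "ii_prior_record",
    "iii_later_prescription",
    "iv_drug_change",
    "v_regularity",
    "vi_min_baseline",
    "drug_group_size",
]


@dataclass
class ScenarioConfig:
    """Window widths and thresholds of one filtering scenario.

    ``stringent`` uses a 90-day baseline lookback and an 18-month post
    ceiling; ``lenient`` a 365-day lookback and a 2-year ceiling.  The
    baseline window is inclusive at both ends (including the +7 days after
    start); the post window is half-open ``[start+183, start+post_max)``.
    """

    mode: str = "lenient"
    measure_mode: str = "average"
    baseline_lookback_days: int | None = None  # 90 stringent / 365 lenient
    baseline_after_days: int = 7
    post_min_days: int = 183
    post_max_days: int | None = None  # 548 stringent / 730 lenient
    comed_exclusion_days: int = 365
    prior_record_days: int = 730
    regularity_window_days: int = 61
    regularity_threshold: float = 0.8
    regularity_mode: str = "windows"  # or "min_one": >=1 prescription start..post
    min_baseline: dict[str, float] = field(default_factory=lambda: {"LDL": 2.0})
    min_cohort_size: int = 500
    min_drug_group_size: int = 20
    addon_rules: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("stringent", "lenient"):
            raise ValueError("mode must be 'stringent' or 'lenient'")
        if self.measure_mode not in ("single", "average"):
            raise ValueError("measure_mode must be 'single' or 'average'")
        if self.baseline_lookback_days is None:
            self.baseline_lookback_days = 90 if self.mode == "stringent" else 365
        if self.post_max_days is None:
            self.post_max_days = 548 if self.mode == "stringent" else 730
        if self.post_min_days >= self.post_max_days:
            raise ValueError("post_min_days must be smaller than post_max_days")
        if self.baseline_lookback_days <= 0:
            raise ValueError("baseline lookback must be positive")
        if not (0.0 <= self.regularity_threshold <= 1.0):
            raise ValueError("regularity_threshold must lie in [0, 1]")


@dataclass
class Regimen:
    """Reconstructed medication regimen of one person."""

    person_id: str
    start_date: int
    start_drug_type: str
    start_dose_mg: float | None
    switch_events: list[tuple[int, str]] = field(default_factory=list)
    regularity: float | None = None
    addon_flags: dict[str, bool] = field(default_factory=dict)
    comed_violation: str | None = None


def classify_prescriptions(
    records: pd.DataFrame, code_map: CodeMap, primary: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag each prescription with its class membership relative to ``primary``.

    Adds columns broad_class, ingredient, is_primary, is_same_class_other,
    is_combination.  Unresolvable codes are quarantined, not dropped.
    """
    known = records["code"].isin(code_map.entries)
    rejects = records.loc[~known].assign(reason="unknown_code")
    out = records.loc[known].copy()
    primary_class = {e.broad_class for e in code_map.entries.values() if e.primary == primary}
    if not primary_class:
        raise ValueError(f"no codes map to primary medication {primary!r}")
    (primary_class,) = primary_class

    entries = out["code"].map(code_map.entries.get)
    out["broad_class"] = [e.broad_class for e in entries]
    out["ingredient"] = [e.ingredient for e in entries]
    out["is_combination"] = [e.is_combination for e in entries]
    out["is_primary"] = [(e.primary == primary and not e.is_combination) for e in entries]
    out["is_same_class_other"] = [
        e.broad_class == primary_class and e.primary != primary and not e.is_combination
        for e in entries
    ]
    return out.reset_index(drop=True), rejects.reset_index(drop=True)


_DOSE_RE = re.compile(r"(\d+(?:\.\d+)?)\s?mg\b", re.IGNORECASE)


def parse_dose(description: str) -> float | None:
    """First ``<number>[ ]mg`` pattern in the free-text description, else None."""
    m = _DOSE_RE.search(description or "")
    return float(m.group(1)) if m else None


def impute_missing_dose(regimens: list[Regimen]) -> list[Regimen]:
    """Fill missing start doses with the per-drug-type median of observed doses.

    A drug type with no observed dose at all leaves the dose missing; the
    person stays in the cohort but is excluded from the dose covariate.
    """
    by_type: dict[str, list[float]] = {}
    for r in regimens:
        if r.start_dose_mg is not None:
            by_type.setdefault(r.start_drug_type, []).append(r.start_dose_mg)
    medians = {t: float(np.median(v)) for t, v in by_type.items()}
    for r in regimens:
        if r.start_dose_mg is None and r.start_drug_type in medians:
            r.start_dose_mg = medians[r.start_drug_type]
    return regimens


def build_regimen(
    prescriptions: pd.DataFrame,
    scenario: ScenarioConfig,
    primary: str,
) -> Regimen | None:
    """Reconstruct one person's regimen from its classified prescriptions.

    Start is the earliest primary-medication prescription.  Any same-class
    non-primary drug within ``comed_exclusion_days`` of start is a violation,
    unless in lenient mode it is an allowed add-on present both before and
    after start (then it becomes a covariate flag).  Combination products
    always violate.  Switches compare consecutive primary prescriptions'
    ingredient and parsed dose.
    """
    rx = prescriptions.sort_values(["date", "code"], kind="mergesort")
    prim = rx[rx["is_primary"]]
    if prim.empty:
        return None  # not a candidate
    start = int(prim["date"].iloc[0])
    start_ing = prim["ingredient"].iloc[0]
    start_dose = parse_dose(prim["description"].iloc[0])

    switches: list[tuple[int, str]] = []
    prev_ing, prev_dose = start_ing, start_dose
    for _, row in prim.iloc[1:].iterrows():
        ing, dose = row["ingredient"], parse_dose(row["description"])
        if ing != prev_ing:
            switches.append((int(row["date"]), "type_change"))
        elif dose is not None and prev_dose is not None and dose != prev_dose:
            switches.append((int(row["date"]), "dose_change"))
        prev_ing, prev_dose = ing, dose if dose is not None else prev_dose

    reg = Regimen(
        person_id=str(rx["person_id"].iloc[0]),
        start_date=start,
        start_drug_type=start_ing,
        start_dose_mg=start_dose,
        switch_events=switches,
    )

    if bool(rx["is_combination"].any()):
        reg.comed_violation = "combination_product"
        return reg

    allowed = scenario.addon_rules.get(primary, set()) if scenario.mode == "lenient" else set()
    others = rx[rx["is_same_class_other"]]
    for ing, grp in others.groupby("ingredient"):
        near = grp[(grp["date"] >= start - scenario.comed_exclusion_days) & (grp["date"] <= start + scenario.comed_exclusion_days)]
        if near.empty:
            continue
        if ing in allowed and (grp["date"] <= start).any() and (grp["date"] >= start).any():
            reg.addon_flags[ing] = True  # consistently taken pre and post
        else:
            reg.comed_violation = "same_class_comedication"
            return reg
    return reg


def regularity(
    rx_dates: np.ndarray | list[int],
    start: int,
    end: int,
    window_days: int = 61,
) -> float:
    """Fraction of consecutive windows in [start, end) holding a prescription.

    ``[start, end)`` is cut into ``window_days``-day windows; a trailing
    partial window counts if at least half the window length.  An adherence
    proxy: 1.0 means every two-month window contained a refill.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    dates = np.asarray(rx_dates, dtype=float)
    span = end - start
    n_full, rem = divmod(span, window_days)
    n_windows = int(n_full) + (1 if rem >= window_days / 2.0 else 0)
    if n_windows == 0:
        n_windows = 1  # interval shorter than half a window: one partial window
    covered = 0
    for w in range(n_windows):
        lo = start + w * window_days
        hi = min(lo + window_days, end) if w == n_windows - 1 else lo + window_days
        if np.any((dates >= lo) & (dates < hi)):
            covered += 1
    return covered / n_windows


def select_window_measure(
    measures: pd.DataFrame,
    start: int,
    scenario: ScenarioConfig,
    which: str,
) -> tuple[float, float, int] | None:
    """Pick the baseline or post value per the scenario's window and mode.

    Baseline window: ``[start - lookback, start + 7]`` inclusive at both ends.
    Post window: ``[start + post_min, start + post_max)``.  Mode ``single``
    takes the measure closest to start (baseline ties resolved to the earlier,
    pre-treatment measure); ``average`` the mean of all in-window values with
    their mean date.  Returns ``(value, date, n_in_window)`` or None.
    """
    dates = measures["date"].to_numpy()
    values = measures["value"].to_numpy(dtype=float)
    if which == "baseline":
        mask = (dates >= start - scenario.baseline_lookback_days) & (
            dates <= start + scenario.baseline_after_days
        )
    elif which == "post":
        mask = (dates >= start + scenario.post_min_days) & (dates < start + scenario.post_max_days)
    else:
        raise ValueError("which must be 'baseline' or 'post'")
    if not mask.any():
        return None
    d, v = dates[mask], values[mask]
    n = int(mask.sum())
    if scenario.measure_mode == "average":
        return float(v.mean()), float(d.mean()), n
    if which == "baseline":
        order = np.lexsort((d, np.abs(d - start)))  # closest; earlier wins ties
    else:
        order = np.argsort(d, kind="stable")  # earliest in post window
    k = order[0]
    return float(v[k]), float(d[k]), n


def qc_cascade(
    measures: pd.DataFrame,
    prescriptions: pd.DataFrame,
    code_map: CodeMap,
    scenario: ScenarioConfig,
    biomarker: str,
    primary: str,
    persons: pd.DataFrame | None = None,
    logger=None,
) -> tuple[pd.DataFrame, QCAudit]:
    """Apply the full exclusion cascade and emit (cohort, audit).

    ``persons`` optionally supplies sex and age-at-epoch covariates.  A final
    cohort below ``min_cohort_size`` is still emitted, with the audit's
    ``cohort_size_warning`` raised.
    """
    rx, _rejects = classify_prescriptions(prescriptions, code_map, primary)
    bm = measures[measures["biomarker"] == biomarker]
    persons_idx = persons.set_index("person_id") if persons is not None else None

    meas_by_person = dict(tuple(measures.groupby("person_id")))
    bm_by_person = dict(tuple(bm.groupby("person_id")))
    rx_by_person = dict(tuple(rx.groupby("person_id")))

    candidates = sorted(pid for pid, g in rx_by_person.items() if g["is_primary"].any())
    first_failing: dict[str, str] = {}
    rows: list[dict] = []
    regimens: dict[str, Regimen] = {}

    for pid in candidates:
        prx = rx_by_person[pid]
        reg = build_regimen(prx, scenario, primary)
        assert reg is not None
        regimens[pid] = reg
        start = reg.start_date

        if reg.comed_violation is not None:
            first_failing[pid] = "comedication"
            continue

        pm = bm_by_person.get(pid)
        base = select_window_measure(pm, start, scenario, "baseline") if pm is not None else None
        post = select_window_measure(pm, start, scenario, "post") if pm is not None else None
        if base is None or post is None:
            first_failing[pid] = "i_measures"
            continue
        base_value, base_date, n_base = base
        post_value, post_date, n_post = post

        allm = meas_by_person.get(pid)
        old_measure = allm is not None and bool((allm["date"] <= start - scenario.prior_record_days).any())
        old_rx = bool((prx.loc[~prx["is_primary"], "date"] <= start - scenario.prior_record_days).any())
        if not (old_measure or old_rx):
            first_failing[pid] = "ii_prior_record"
            continue

        if not bool((prx["date"] > post_date).any()):
            first_failing[pid] = "iii_later_prescription"
            continue

        kinds = {k for d, k in reg.switch_events if start < d <= post_date}
        changed = ("type_change" in kinds) or (scenario.mode == "stringent" and "dose_change" in kinds)
        if changed:
            first_failing[pid] = "iv_drug_change"
            continue

        prim_dates = prx.loc[prx["is_primary"], "date"].to_numpy()
        if scenario.regularity_mode == "min_one":
            ok = bool(np.any((prim_dates > start) & (prim_dates < post_date)))
            reg.regularity = 1.0 if ok else 0.0
        else:
            reg.regularity = regularity(prim_dates, start, int(np.ceil(post_date)), scenario.regularity_window_days)
            ok = reg.regularity >= scenario.regularity_threshold
        if not ok:
            first_failing[pid] = "v_regularity"
            continue

        floor = scenario.min_baseline.get(biomarker)
        if floor is not None and base_value < floor:
            first_failing[pid] = "vi_min_baseline"
            continue

        row = {
            "person_id": pid,
            "baseline_value": base_value,
            "baseline_date": base_date,
            "n_baseline_measures": n_base,
            "post_value": post_value,
            "post_date": post_date,
            "n_post_measures": n_post,
            "time_start_to_post": post_date - start,
            "start_date": start,
            "drug_type": reg.start_drug_type,
            "dose_mg": reg.start_dose_mg,
            "regularity": reg.regularity,
        }
        for addon in scenario.addon_rules.get(primary, set()):
            row[f"addon_{addon}"] = bool(reg.addon_flags.get(addon, False))
        if persons_idx is not None and pid in persons_idx.index:
            row["sex"] = persons_idx.loc[pid, "sex"]
            row["age_at_start"] = float(persons_idx.loc[pid, "age0"]) + start / 365.25
        rows.append(row)

    cohort = pd.DataFrame(rows)
    if not cohort.empty:
        impute_missing_dose([regimens[p] for p in cohort["person_id"]])
        cohort["dose_mg"] = [regimens[p].start_dose_mg for p in cohort["person_id"]]
        counts = cohort["drug_type"].value_counts()
        small = counts[counts < scenario.min_drug_group_size].index
        dropped = cohort["person_id"][cohort["drug_type"].isin(small)]
        for pid in dropped:
            first_failing[pid] = "drug_group_size"
        cohort = cohort[~cohort["drug_type"].isin(small)].reset_index(drop=True)

    removed = {s: 0 for s in QC_STAGES}
    for stage in first_failing.values():
        removed[stage] += 1
    audit = QCAudit(
        stages=list(QC_STAGES),
        removed=removed,
        first_failing=first_failing,
        n_input=len(candidates),
        n_final=len(cohort),
        cohort_size_warning=len(cohort) < scenario.min_cohort_size,
    )
    if logger is not None:
        for s in QC_STAGES:
            logger.info("QC stage %s: removed %d", s, removed[s])
        logger.info("QC survivors: %d of %d", audit.n_final, audit.n_input)
    return cohort, audit


def control_pairs(
    measures: pd.DataFrame,
    biomarker: str,
    min_spacing: int = 183,
    max_spacing: int = 1095,
) -> pd.DataFrame:
    """First/second measure pairs of drug-naive persons within the spacing band.

    For each person the earliest qualifying pair is chosen: the first measure,
    and the earliest later measure whose spacing falls in
    ``[min_spacing, max_spacing]`` days.  Persons without such a pair drop out.
    """
    rows = []
    for pid, grp in measures[measures["biomarker"] == biomarker].groupby("person_id"):
        grp = grp.sort_values("date", kind="mergesort")
        dates = grp["date"].to_numpy()
        values = grp["value"].to_numpy(dtype=float)
        found = False
        for i in range(len(dates)):
            gaps = dates - dates[i]
            ok = np.where((gaps >= min_spacing) & (gaps <= max_spacing))[0]
            if len(ok):
                j = ok[0]
                rows.append(
                    {
                        "person_id": pid,
                        "baseline_value": values[i],
                        "baseline_date": int(dates[i]),
                        "post_value": values[j],
                        "post_date": int(dates[j]),
                        "time_start_to_post": int(dates[j] - dates[i]),
                    }
                )
                found = True
                break
        if found:
            continue
    return pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "baseline_value",
            "baseline_date",
            "post_value",
            "post_date",
            "time_start_to_post",
        ],
    )
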