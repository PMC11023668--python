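"""Per-variant association models for drug-response phenotypes.

The estimand is the pharmacogenetic effect gamma_D: under the longitudinal
model the biomarker difference satisfies

    dY = beta_D + gamma_D * G + delta,

so an ordinary least-squares regression of the (covariate-adjusted)
difference on allele dosage estimates gamma_D without bias, whatever the
variant's baseline effect beta_0.  Appending baseline levels to the
covariates ("baseline_adjusted") reintroduces a beta_0-driven bias; both
model variants are provided, together with the drug-naive longitudinal-change
negative control, so the bias signature can be measured directly.

The module is organised statsmodels-style: :class:`DrugResponseGWAS` is
built from data and ``fit()`` returns a :class:`DrugResponseGWASResults`
carrying the per-variant table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import adjust_covariates, response

__all__ = [
    "AssociationResult",
    "DrugResponseGWAS",
    "DrugResponseGWASResults",
    "MODEL_VARIANTS",
    "bonferroni_threshold",
    "count_below",
    "directional_concordance",
    "genotype_stratified_summary",
    "scan",
    "variant_association",
]

MODEL_VARIANTS = ("unadjusted", "baseline_adjusted", "control_change", "control_change_adjusted")


@dataclass(frozen=True)
class AssociationResult:
    """One fitted variant x model combination."""

    variant_id: str
    model_variant: str
    mode: str
    beta: float
    se: float
    p: float
    n: int
    eaf: float
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


def variant_association(
    resp: np.ndarray,
    dosage: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    baseline: np.ndarray | None = None,
    model_variant: str = "unadjusted",
    variant_id: str = "variant",
    mode: str = "absolute",
) -> AssociationResult:
    """OLS fit of the response on dosage (+ covariates, + baseline if adjusted).

    ``control_change`` variants use the same machinery on drug-naive pairs;
    the ``*_adjusted`` variants append baseline to the covariate set.  Effect
    allele is the counted allele of the dosage, so flipping dosage to 2 - g
    flips beta's sign exactly.  Monomorphic dosages are flagged, not fitted.
    """
    if model_variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {model_variant!r}")
    resp = np.asarray(resp, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    keep = np.isfinite(resp) & np.isfinite(dosage)
    if baseline is not None:
        baseline = np.asarray(baseline, dtype=float)
        keep &= np.isfinite(baseline)
    resp, dosage = resp[keep], dosage[keep]
    eaf = float(dosage.mean() / 2.0) if len(dosage) else np.nan

    if len(dosage) == 0 or np.ptp(dosage) == 0:
        return AssociationResult(variant_id, model_variant, mode, np.nan, np.nan, np.nan, len(dosage), eaf, "monomorphic")

    X = [dosage]
    names = ["dosage"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[keep]
        if cov.ndim == 1:
            cov = cov[:, None]
        X.append(cov)
        names += [f"c{j}" for j in range(cov.shape[1])]
    if model_variant.endswith("adjusted") and model_variant != "unadjusted":
        if baseline is None:
            raise ValueError("baseline required for a baseline-adjusted model")
        X.append(baseline[keep][:, None])
        names.append("baseline")
    design = sm.add_constant(np.column_stack(X))
    if len(resp) < design.shape[1] + 2:
        return AssociationResult(variant_id, model_variant, mode, np.nan, np.nan, np.nan, len(resp), eaf, "n_too_small")
    fit = sm.OLS(resp, design).fit()
    return AssociationResult(
        variant_id,
        model_variant,
        mode,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=int(len(resp)),
        eaf=eaf,
    )


def scan(
    cohort: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    model_variants: tuple[str, ...] = ("unadjusted", "baseline_adjusted"),
    modes: tuple[str, ...] = ("absolute", "log_relative"),
) -> pd.DataFrame:
    """One row per variant x model variant x response mode, deterministic order.

    ``cohort`` must carry baseline_value/post_value (or the control pair
    equivalents); ``dosages`` is person-indexed.  Variants are ordered by id,
    then model, then mode.
    """
    dos = dosages.loc[cohort["person_id"]]
    base = cohort["baseline_value"].to_numpy(dtype=float)
    post = cohort["post_value"].to_numpy(dtype=float)
    rows = []
    for vid in dosages.columns:
        g = dos[vid].to_numpy(dtype=float)
        for model in model_variants:
            for mode in modes:
                y = response(base, post, mode)
                r = variant_association(y, g, covariates, base, model, vid, mode)
                rows.append(
                    {
                        "variant_id": r.variant_id,
                        "model": r.model_variant,
                        "mode": r.mode,
                        "beta": r.beta,
                        "se": r.se,
                        "p": r.p,
                        "n": r.n,
                        "eaf": r.eaf,
                        "flag": r.flag or "",
                    }
                )
    out = pd.DataFrame(rows)
    return out.sort_values(["variant_id", "model", "mode"], kind="mergesort").reset_index(drop=True)


class DrugResponseGWAS:
    """Drug-response association model over a variant panel.

    Parameters
    ----------
    cohort : DataFrame with person_id, baseline_value, post_value
    dosages : person-indexed DataFrame of allele dosages in [0, 2]
    covariates : optional person-aligned covariate matrix (never baseline)
    model_variants, modes : which regressions to fit per variant
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        dosages: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        model_variants: tuple[str, ...] = ("unadjusted", "baseline_adjusted"),
        modes: tuple[str, ...] = ("absolute", "log_relative"),
    ):
        missing = set(cohort["person_id"]) - set(dosages.index)
        if missing:
            raise ValueError(f"{len(missing)} cohort persons lack dosages")
        self.cohort = cohort.reset_index(drop=True)
        self.dosages = dosages
        self.covariates = covariates
        self.model_variants = tuple(model_variants)
        self.modes = tuple(modes)

    @classmethod
    def from_dataframes(cls, cohort, dosages, covariates=None, **kw) -> "DrugResponseGWAS":
        return cls(cohort, dosages, covariates, **kw)

    def fit(self) -> "DrugResponseGWASResults":
        table = scan(self.cohort, self.dosages, self.covariates, self.model_variants, self.modes)
        return DrugResponseGWASResults(self, table)


class DrugResponseGWASResults:
    """Estimates, uncertainties and diagnostics from a fitted panel scan."""

    def __init__(self, model: DrugResponseGWAS, table: pd.DataFrame):
        self.model = model
        self.table = table

    def significant(self, alpha: float = 0.05, bonferroni: bool = True) -> pd.DataFrame:
        m = self.table["variant_id"].nunique()
        thr = bonferroni_threshold(alpha, m) if bonferroni else alpha
        return self.table[self.table["p"] < thr]

    def summary(self) -> str:
        t = self.table
        lines = [
            "Drug-response association scan",
            f"  variants: {t['variant_id'].nunique()}   models: {sorted(t['model'].unique())}",
            f"  cohort n: {len(self.model.cohort)}",
            "",
            t.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def count_below(p_values, threshold: float) -> int:
    """Number of p-values strictly below the threshold."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any()):
        raise ValueError("p-values must be finite and in (0, 1]")
    return int((p < threshold).sum())


def directional_concordance(discovery_betas, replication_betas, mask=None) -> int:
    """Masked pairs whose effect estimates share a sign.

    A zero beta counts as discordant (with a warning): its direction is
    undefined.
    """
    d = np.asarray(discovery_betas, dtype=float)
    r = np.asarray(replication_betas, dtype=float)
    if d.shape != r.shape:
        raise ValueError("beta vectors must align")
    m = np.ones(len(d), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if (d[m] == 0).any() or (r[m] == 0).any():
        import warnings

        warnings.warn("zero beta treated as discordant")
    return int((np.sign(d[m]) * np.sign(r[m]) > 0).sum())


def genotype_stratified_summary(
    treated: pd.DataFrame,
    controls: pd.DataFrame,
    treated_dosage: np.ndarray,
    control_dosage: np.ndarray,
    treated_covariates: pd.DataFrame | np.ndarray | None = None,
    control_covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean/SD/n of standardized outcomes per genotype, group and model.

    Outcomes per group: the sex/age-adjusted standardized baseline, and the
    standardized change (post - baseline), residualized on the group's
    covariates, once without (correct model) and once with (biased model)
    baseline among the covariates.  Dosages are rounded to genotype classes
    {0, 1, 2}.  Cells without carriers report n=0 and no mean.
    """

    def _z(values, cov, extra=None):
        X = None
        if cov is not None:
            X = np.asarray(cov, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        if extra is not None:
            extra = np.asarray(extra, dtype=float)[:, None]
            X = extra if X is None else np.column_stack([X, extra])
        r = adjust_covariates(np.asarray(values, dtype=float), X)
        sd = r.std(ddof=1)
        return r / sd if sd > 0 else r

    rows = []
    for group, df, dose, cov in (
        ("treated", treated, treated_dosage, treated_covariates),
        ("control", controls, control_dosage, control_covariates),
    ):
        base = df["baseline_value"].to_numpy(dtype=float)
        change = df["post_value"].to_numpy(dtype=float) - base
        outcomes = {
            "baseline": _z(base, cov),
            "change_unadjusted": _z(change, cov),
            "change_adjusted": _z(change, cov, extra=base),
        }
        geno = np.clip(np.round(np.asarray(dose, dtype=float)), 0, 2).astype(int)
        for outcome, z in outcomes.items():
            for g in (0, 1, 2):
                sel = geno == g
                n = int(sel.sum())
                rows.append(
                    {
                        "group": group,
                        "outcome": outcome,
                        "genotype": g,
                        "n": n,
                        "mean": float(z[sel].mean()) if n else np.nan,
                        "sd": float(z[sel].std(ddof=1)) if n > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
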