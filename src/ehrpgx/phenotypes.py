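"""Drug-response outcome derivation: differences, residualization, transforms.

The response phenotype is the absolute (post - baseline) or logarithmic
relative (log post - log baseline) biomarker difference.  The difference is
adjusted for study covariates (sex, age at start, time start-to-post, drug
type and dose, add-on flags, confounder components) but never for baseline
levels: baseline adjustment biases genetic effect estimates whenever a
variant also affects baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "adjust_covariates",
    "build_covariates",
    "derive_phenotypes",
    "hba1c_convert",
    "inverse_normal_transform",
    "response",
]


def response(baseline, post, mode: str):
    """Absolute or log-relative difference of post vs baseline levels.

    ``log_relative`` requires strictly positive values; offending entries
    come back NaN and should be dropped with a reason by the caller.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if mode == "absolute":
        out = post - baseline
    elif mode == "log_relative":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where((baseline > 0) & (post > 0), np.log(post) - np.log(baseline), np.nan)
    else:
        raise ValueError("mode must be 'absolute' or 'log_relative'")
    return out if out.ndim else float(out)


def adjust_covariates(values, covariates: pd.DataFrame | np.ndarray | None) -> np.ndarray:
    """Residuals of least-squares on covariates plus an intercept.

    Aliased (rank-deficient) columns are harmless: lstsq's minimum-norm
    solution leaves the residuals orthogonal to the whole column space.
    """
    y = np.asarray(values, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("covariate matrix is rank-deficient; aliased columns ignored")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset by default.

    Maps value of rank r (ties get mean ranks) to the normal quantile at
    ``(r - offset) / (n + 1 - 2*offset)``; with the Blom offset this is
    ``(r - 3/8)/(n + 1/4)``.
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 values")
    if np.all(y == y[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - offset) / (len(y) + 1 - 2 * offset))


# NGSP / IFCC master equation: NGSP(%) = 0.09148 * IFCC(mmol/mol) + 2.152
_HBA1C_SLOPE = 0.09148
_HBA1C_INTERCEPT = 2.152


def hba1c_convert(value, from_unit: str, to_unit: str):
    """Convert HbA1c between IFCC mmol/mol and NGSP percent."""
    units = {"mmol_per_mol", "percent"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"units must be in {sorted(units)}")
    value = np.asarray(value, dtype=float)
    if from_unit == to_unit:
        out = value
    elif from_unit == "mmol_per_mol":
        out = _HBA1C_SLOPE * value + _HBA1C_INTERCEPT
    else:
        out = (value - _HBA1C_INTERCEPT) / _HBA1C_SLOPE
    return out if out.ndim else float(out)


def build_covariates(
    cohort: pd.DataFrame,
    n_confounders: int = 4,
    seed: int | None = None,
    confounders: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate matrix from a cohort table.

    Uses whichever of sex, age_at_start, time_start_to_post, drug-type
    indicators (first level dropped), dose and add-on flags are present.
    ``confounders`` stands in for genotype principal components; if absent
    and ``seed`` given, ``n_confounders`` standard-normal columns are drawn.
    """
    cols: dict[str, np.ndarray] = {}
    n = len(cohort)
    for c in ("sex", "age_at_start", "time_start_to_post"):
        if c in cohort.columns:
            cols[c] = cohort[c].to_numpy(dtype=float)
    if "drug_type" in cohort.columns and cohort["drug_type"].nunique() > 1:
        dummies = pd.get_dummies(cohort["drug_type"], prefix="drug", drop_first=True)
        for c in dummies.columns:
            cols[c] = dummies[c].to_numpy(dtype=float)
    if "dose_mg" in cohort.columns and cohort["dose_mg"].notna().all():
        cols["dose_mg"] = cohort["dose_mg"].to_numpy(dtype=float)
    for c in cohort.columns:
        if c.startswith("addon_"):
            cols[c] = cohort[c].to_numpy(dtype=float)
    if confounders is not None:
        for k in range(confounders.shape[1]):
            cols[f"pc{k + 1}"] = confounders[:, k]
    elif seed is not None and n_confounders > 0:
        rng = np.random.default_rng(seed)
        for k in range(n_confounders):
            cols[f"pc{k + 1}"] = rng.normal(size=n)
    return pd.DataFrame(cols, index=cohort.index)


def derive_phenotypes(
    cohort: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-person response phenotypes in every mode.

    Columns: person_id, response_abs, response_logrel, residual_abs,
    residual_logrel, int_abs, int_logrel.  Rows whose values preclude the
    log-relative mode keep NaN there (and in its derived columns).
    """
    out = pd.DataFrame({"person_id": cohort["person_id"]})
    out["response_abs"] = response(cohort["baseline_value"], cohort["post_value"], "absolute")
    out["response_logrel"] = response(cohort["baseline_value"], cohort["post_value"], "log_relative")
    for mode in ("abs", "logrel"):
        y = out[f"response_{mode}"].to_numpy()
        ok = np.isfinite(y)
        resid = np.full(len(y), np.nan)
        cov = covariates.loc[ok] if covariates is not None else None
        resid[ok] = adjust_covariates(y[ok], cov)
        out[f"residual_{mode}"] = resid
        tr = np.full(len(y), np.nan)
        if ok.sum() >= 2 and np.unique(resid[ok]).size > 1:
            tr[ok] = inverse_normal_transform(resid[ok])
        out[f"int_{mode}"] = tr
    order = [
        "person_id",
        "response_abs",
        "response_logrel",
        "residual_abs",
        "residual_logrel",
        "int_abs",
        "int_logrel",
    ]
    return out[order]
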