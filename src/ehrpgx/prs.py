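"""Polygenic-score analyses of drug response.

Scores are per-person weighted allele-dosage sums standardized to mean 0,
SD 1 in the analysis sample, so associations are reported per 1 SD of PRS
and are invariant to affine transforms of the raw score.  The stratification
and variance-explained analyses mirror the treated-cohort views: response by
PRS-adjusted-baseline quantile x PRS quintile (optionally x one variant's
genotype), and nested-model in-sample R^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "baseline_adjusted_for_prs",
    "compute_prs",
    "prs_response_association",
    "quantile_bins",
    "stratification_table",
    "variance_explained",
]


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Standardized weighted allele-dosage sum.

    Every weight variant must be present in the dosage panel; a raw score
    with zero variance cannot be standardized and raises.
    """
    missing = [v for v in weights["variant_id"] if v not in dosages.columns]
    if missing:
        raise KeyError(f"weight variants missing from dosage panel: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    w = weights.set_index("variant_id")["weight"]
    raw = dosages[w.index].to_numpy(dtype=float) @ w.to_numpy(dtype=float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("raw PRS has zero variance; cannot standardize")
    return pd.Series((raw - raw.mean()) / sd, index=dosages.index, name="prs")


def prs_response_association(
    resp: np.ndarray,
    prs: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    adjust_baseline: bool = False,
    baseline: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(beta per SD PRS, SE, p) from OLS of the response on standardized PRS."""
    resp = np.asarray(resp, dtype=float)
    prs = np.asarray(prs, dtype=float)
    keep = np.isfinite(resp) & np.isfinite(prs)
    cols = [prs]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    if adjust_baseline:
        if baseline is None:
            raise ValueError("baseline required when adjust_baseline=True")
        cols.append(np.asarray(baseline, dtype=float)[:, None])
    X = sm.add_constant(np.column_stack([np.asarray(c)[keep] if np.asarray(c).ndim == 1 else np.asarray(c)[keep] for c in cols]))
    fit = sm.OLS(resp[keep], X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def baseline_adjusted_for_prs(baseline: np.ndarray, prs: np.ndarray) -> np.ndarray:
    """Residuals of baseline on PRS + intercept.

    Removes the genetically predicted part of baseline so the residual more
    closely reflects the environmental component.
    """
    baseline = np.asarray(baseline, dtype=float)
    X = sm.add_constant(np.asarray(prs, dtype=float))
    return np.asarray(sm.OLS(baseline, X).fit().resid)


def quantile_bins(values: np.ndarray, q: int) -> np.ndarray:
    """Equal-count quantile bins 0..q-1, ties broken by rank order.

    Boundary values go to the lower bin by construction of the rank split.
    """
    if q < 2:
        raise ValueError("need at least 2 quantile groups")
    ranks = stats.rankdata(values, method="ordinal") - 1
    return np.minimum((ranks * q) // len(values), q - 1).astype(int)


def stratification_table(
    cohort: pd.DataFrame,
    prs: np.ndarray,
    q_baseline: int = 5,
    q_prs: int = 5,
    variant_dosage: np.ndarray | None = None,
    min_cell_n: int = 1,
) -> pd.DataFrame:
    """Mean response per (PRS-adjusted-baseline quantile x PRS quintile) cell.

    Optionally stratifies further by one variant's genotype class, dropping
    cells below ``min_cell_n`` carriers.  Cell columns: mean_abs, mean_rel, n.
    """
    base = cohort["baseline_value"].to_numpy(dtype=float)
    post = cohort["post_value"].to_numpy(dtype=float)
    prs = np.asarray(prs, dtype=float)
    adj_base = baseline_adjusted_for_prs(base, prs)
    b_bin = quantile_bins(adj_base, q_baseline)
    p_bin = quantile_bins(prs, q_prs)
    abs_resp = post - base
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_resp = np.where((base > 0) & (post > 0), np.log(post / base), np.nan)
    frame = {
        "baseline_bin": b_bin,
        "prs_bin": p_bin,
        "abs": abs_resp,
        "rel": rel_resp,
    }
    keys = ["baseline_bin", "prs_bin"]
    if variant_dosage is not None:
        frame["genotype"] = np.clip(np.round(np.asarray(variant_dosage, dtype=float)), 0, 2).astype(int)
        keys.append("genotype")
    df = pd.DataFrame(frame)
    out = (
        df.groupby(keys)
        .agg(mean_abs=("abs", "mean"), mean_rel=("rel", "mean"), n=("abs", "size"))
        .reset_index()
    )
    return out[out["n"] >= min_cell_n].reset_index(drop=True)


def variance_explained(
    resp: np.ndarray, blocks: list[tuple[str, np.ndarray]]
) -> pd.DataFrame:
    """In-sample R^2 of nested OLS models grown block by block.

    ``blocks`` is an ordered list of (name, column or matrix); model k uses
    blocks 1..k plus an intercept.  R^2 never decreases along the sequence.
    """
    resp = np.asarray(resp, dtype=float)
    keep = np.isfinite(resp)
    rows = []
    cols: list[np.ndarray] = []
    for name, block in blocks:
        b = np.asarray(block, dtype=float)
        if b.ndim == 1:
            b = b[:, None]
        cols.append(b)
        X = sm.add_constant(np.column_stack(cols)[keep])
        fit = sm.OLS(resp[keep], X).fit()
        rows.append({"model": name, "r2": float(fit.rsquared), "n_params": X.shape[1]})
    return pd.DataFrame(rows)
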