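import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ehrpgx.generate import GenerativeParams, PRSArchitecture, simulate_response_cohort
from ehrpgx.prs import (
    baseline_adjusted_for_prs,
    compute_prs,
    prs_response_association,
    quantile_bins,
    stratification_table,
    variance_explained,
)


@pytest.fixture(scope="module")
def ldl_like_cohort():
    """Log-scale biomarker, polygenic baseline, PRS-linked PGx penalty."""
    params = GenerativeParams(
        scale="log",
        intercept=float(np.log(4.5)),
        betaD=-0.35,
        betaE=1.0,
        var_env_persistent=0.02,
        var_env_occasion=0.03,
        variants=[],
        prs_arch=PRSArchitecture(n_variants=150, var_baseline=0.0225),
        prs_gammaD=0.03,
    )
    df = simulate_response_cohort(20_000, params, seed=51)
    return df.rename(columns={"baseline": "baseline_value", "post": "post_value"})


class TestComputePrs:
    @staticmethod
    def _panel(seed=0, n=500, m=4):
        rng = np.random.default_rng(seed)
        dosages = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, m)).astype(float),
            index=pd.Index([f"P{i}" for i in range(n)], name="person_id"),
            columns=[f"v{j}" for j in range(m)],
        )
        weights = pd.DataFrame(
            {"variant_id": [f"v{j}" for j in range(m)], "effect_allele": "A", "weight": [0.5, -0.2, 0.1, 0.7]}
        )
        return dosages, weights

    def test_single_variant_unit_weight_is_standardized_dosage(self):
        dosages, _ = self._panel()
        w = pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["A"], "weight": [1.0]})
        score = compute_prs(dosages, w)
        g = dosages["v0"].to_numpy()
        assert np.allclose(score, (g - g.mean()) / g.std())

    def test_affine_weight_transform_leaves_score_unchanged(self):
        dosages, weights = self._panel()
        a = compute_prs(dosages, weights)
        doubled = weights.assign(weight=2.0 * weights["weight"])
        assert np.allclose(a, compute_prs(dosages, doubled))

    def test_zero_variance_score_rejected(self):
        dosages, weights = self._panel()
        zeroed = weights.assign(weight=0.0)
        with pytest.raises(ValueError, match="zero variance"):
            compute_prs(dosages, zeroed)

    def test_missing_weight_variants_reported(self):
        dosages, weights = self._panel()
        extra = pd.concat(
            [weights, pd.DataFrame({"variant_id": ["nope"], "effect_allele": ["A"], "weight": [1.0]})]
        )
        with pytest.raises(KeyError, match="nope"):
            compute_prs(dosages, extra)


class TestPrsResponseAssociation:
    def test_multiplicative_drug_effect_gives_negative_absolute_beta(self, ldl_like_cohort):
        df = ldl_like_cohort
        resp = df["post_value"] - df["baseline_value"]
        b, se, p = prs_response_association(resp, df["prs"])
        assert b < -5 * se

    def test_baseline_adjustment_artificially_reverses_the_sign(self, ldl_like_cohort):
        df = ldl_like_cohort
        resp = df["post_value"] - df["baseline_value"]
        b, se, p = prs_response_association(
            resp, df["prs"], adjust_baseline=True, baseline=df["baseline_value"].to_numpy()
        )
        assert b > 5 * se

    def test_relative_response_shows_opposing_sign(self, ldl_like_cohort):
        # the PGx penalty linked to the score lowers the *relative* reduction
        df = ldl_like_cohort
        rel = np.log(df["post_value"] / df["baseline_value"])
        b, se, p = prs_response_association(rel, df["prs"])
        assert b > 5 * se

    def test_noise_score_is_null(self, ldl_like_cohort):
        df = ldl_like_cohort
        rng = np.random.default_rng(52)
        noise = rng.normal(size=len(df))
        resp = df["post_value"] - df["baseline_value"]
        b, se, p = prs_response_association(resp, noise)
        assert abs(b) < 3 * se


class TestBaselineAdjustedForPrs:
    def test_orthogonal_prs_leaves_centered_baseline(self):
        rng = np.random.default_rng(53)
        base = rng.normal(4.0, 1.0, size=2000)
        prs = rng.normal(size=2000)
        resid = baseline_adjusted_for_prs(base, prs)
        centered = base - base.mean()
        assert np.corrcoef(resid, centered)[0, 1] > 0.999
        # the fitted slope on an orthogonal score shrinks with 1/sqrt(n)
        assert np.abs(resid - centered).max() < 5 * base.std() / np.sqrt(len(base)) * np.abs(prs).max()

    def test_linear_baseline_fully_removed(self):
        prs = np.linspace(-2, 2, 100)
        resid = baseline_adjusted_for_prs(3.0 + 0.8 * prs, prs)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_prs(self):
        rng = np.random.default_rng(54)
        prs = rng.normal(size=1000)
        base = 4.0 + 0.5 * prs + rng.normal(size=1000)
        resid = baseline_adjusted_for_prs(base, prs)
        assert abs(prs @ resid) < 1e-8 * len(prs)


class TestStratification:
    def test_quantile_bins_partition_with_lower_bin_ties(self):
        bins = quantile_bins(np.array([1.0, 1.0, 1.0, 2.0, 3.0]), 5)
        assert sorted(bins) == [0, 1, 2, 3, 4]

    def test_null_generator_gives_flat_cells(self):
        params = GenerativeParams(betaD=-1.0, variants=[], var_env_persistent=0.25, var_env_occasion=0.25)
        df = simulate_response_cohort(10_000, params, seed=55).rename(
            columns={"baseline": "baseline_value", "post": "post_value"}
        )
        rng = np.random.default_rng(56)
        prs = rng.normal(size=len(df))  # pure-noise score
        table = stratification_table(df, prs, q_baseline=3, q_prs=5)
        assert table["n"].sum() == len(df)
        # a noise score carries no signal: within each baseline stratum the
        # cell means across score quintiles are statistically indistinguishable
        resp = df["post_value"] - df["baseline_value"]
        mc_se = resp.std() / np.sqrt(table["n"].min())
        for _, block in table.groupby("baseline_bin"):
            centered = block["mean_abs"] - block["mean_abs"].mean()
            assert (np.abs(centered) < 3 * mc_se).all()

    def test_absolute_reduction_monotone_in_prs_at_fixed_baseline(self, ldl_like_cohort):
        df = ldl_like_cohort
        table = stratification_table(df, df["prs"].to_numpy(), q_baseline=3, q_prs=5)
        for _, row_block in table.groupby("baseline_bin"):
            rho = stats.spearmanr(row_block["prs_bin"], row_block["mean_abs"]).statistic
            assert rho < 0  # higher score, stronger absolute reduction

    def test_genotype_stratum_cell_drop_rule(self, ldl_like_cohort):
        df = ldl_like_cohort.head(2000)
        rng = np.random.default_rng(57)
        dose = rng.binomial(2, 0.1, size=len(df)).astype(float)
        table = stratification_table(df, df["prs"].to_numpy()[: len(df)], 2, 2, variant_dosage=dose, min_cell_n=30)
        assert (table["n"] >= 30).all()
        assert "genotype" in table.columns


class TestVarianceExplained:
    def test_nested_r2_never_decreases(self, ldl_like_cohort):
        df = ldl_like_cohort
        resp = (df["post_value"] - df["baseline_value"]).to_numpy()
        prs = df["prs"].to_numpy()
        adj_base = baseline_adjusted_for_prs(df["baseline_value"].to_numpy(), prs)
        r2 = variance_explained(resp, [("adjusted_baseline", adj_base), ("+prs", prs)])
        assert r2["r2"].is_monotonic_increasing
        assert r2["r2"].iloc[1] > r2["r2"].iloc[0]  # the score adds signal here

    def test_perfect_first_block(self):
        rng = np.random.default_rng(58)
        x = rng.normal(size=1000)
        r2 = variance_explained(2.0 * x - 1.0, [("x", x)])
        assert r2["r2"].iloc[0] == pytest.approx(1.0)

    def test_pure_noise_block_adds_almost_nothing(self):
        rng = np.random.default_rng(59)
        n = 10_000
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        noise = rng.normal(size=n)
        r2 = variance_explained(y, [("x", x), ("+noise", noise)])
        assert r2["r2"].iloc[1] - r2["r2"].iloc[0] < 0.01
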