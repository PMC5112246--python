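import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from twindmr.core_io import BetaMatrix, PairDesign
from twindmr.pairmodel import (
    PairDifferences,
    build_projector,
    call_dmps,
    compute_pair_differences,
    fit_cpg_models,
    fold_changes,
)


def _diffs(delta, pair_ids=None):
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    pair_ids = pair_ids or [f"p{i}" for i in range(delta.shape[1])]
    return PairDifferences(
        probe_ids=[f"cg{i}" for i in range(delta.shape[0])],
        pair_ids=pair_ids,
        delta=delta,
        ratio=np.exp(delta),  # placeholder positive ratios
    )


def _design(n, **overrides):
    base = {
        "pair_id": [f"p{i}" for i in range(n)],
        "case_sample": [f"c{i}" for i in range(n)],
        "control_sample": [f"k{i}" for i in range(n)],
        "smoking": [float(i % 2) for i in range(n)],
        "accp": [i % 2 for i in range(n)],
        "dmard": [(i // 2) % 2 for i in range(n)],
        "age": [40.0 + i for i in range(n)],
        "sex": [i % 2 for i in range(n)],
    }
    base.update(overrides)
    return PairDesign(pd.DataFrame(base))


class TestPairDifferences:
    def test_delta_and_ratio_arithmetic(self, small_design):
        values = np.full((1, 8), 0.4)
        values[0, 0] = 0.6  # case of pair 1
        betas = BetaMatrix(["cg0"], ["c1", "k1", "c2", "k2", "c3", "k3", "c4", "k4"], values)
        d = compute_pair_differences(betas, small_design)
        assert d.delta[0, 0] == pytest.approx(0.2)
        assert d.ratio[0, 0] == pytest.approx(1.5)
        assert d.delta[0, 1] == pytest.approx(0.0)
        assert d.ratio[0, 1] == pytest.approx(1.0)

    def test_missing_twin_omits_pair_at_probe(self, small_design):
        values = np.full((1, 8), 0.5)
        values[0, 1] = np.nan  # control of pair 1
        betas = BetaMatrix(["cg0"], ["c1", "k1", "c2", "k2", "c3", "k3", "c4", "k4"], values)
        d = compute_pair_differences(betas, small_design)
        assert np.isnan(d.delta[0, 0])
        assert d.n_pairs_per_probe[0] == 3


class TestFitCpgModels:
    def test_intercept_only_matches_paired_t_closed_form(self):
        deltas = np.array([0.1, 0.2, 0.1, 0.2])
        table = fit_cpg_models(_diffs(deltas), _design(4), covariates=(), min_pairs=3)
        assert table["alpha"].iloc[0] == pytest.approx(0.15)
        t = deltas.mean() / (deltas.std(ddof=1) / np.sqrt(4))
        p = 2 * stats.t.sf(abs(t), df=3)
        assert table["alpha_p"].iloc[0] == pytest.approx(p, rel=1e-12)
        assert table["n_pairs_used"].iloc[0] == 4

    def test_balanced_binary_covariate_recovers_effect(self):
        # exposed pairs get +0.3 on top of a 0.1 baseline delta
        exposure = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        deltas = 0.1 + 0.3 * exposure
        design = _design(6, smoking=exposure)
        table = fit_cpg_models(_diffs(deltas), design, covariates=("smoking",), min_pairs=3)
        assert table["smoking_slope"].iloc[0] == pytest.approx(0.3, abs=1e-12)
        # 0/1 exposure coding: the intercept is the unexposed-pair mean delta
        assert table["alpha"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(11)
        n = 12
        design = _design(n)
        deltas = rng.normal(0, 0.05, n)
        covs = ("smoking", "age")
        table = fit_cpg_models(_diffs(deltas), design, covariates=covs, min_pairs=5)
        smoking = design.table["smoking"].to_numpy(dtype=float)  # binary, raw
        age = design.table["age"].to_numpy(dtype=float)
        X = sm.add_constant(np.column_stack([smoking, age - age.mean()]))
        fit = sm.OLS(deltas, X).fit()
        assert table["alpha"].iloc[0] == pytest.approx(fit.params[0], rel=1e-10)
        assert table["alpha_p"].iloc[0] == pytest.approx(fit.pvalues[0], rel=1e-10)
        assert table["smoking_slope"].iloc[0] == pytest.approx(fit.params[1], rel=1e-10)
        assert table["age_p"].iloc[0] == pytest.approx(fit.pvalues[2], rel=1e-10)

    def test_case_control_swap_negates_alpha_keeps_p(self):
        rng = np.random.default_rng(12)
        deltas = rng.normal(0.02, 0.05, size=(5, 8))
        design = _design(8)
        a = fit_cpg_models(_diffs(deltas), design, covariates=("accp",), min_pairs=4)
        b = fit_cpg_models(_diffs(-deltas), design, covariates=("accp",), min_pairs=4)
        np.testing.assert_allclose(b["alpha"], -a["alpha"], rtol=1e-12)
        np.testing.assert_allclose(b["alpha_p"], a["alpha_p"], rtol=1e-12)

    def test_location_equivariance_of_alpha(self):
        rng = np.random.default_rng(13)
        deltas = rng.normal(0, 0.05, size=(3, 10))
        design = _design(10)
        a = fit_cpg_models(_diffs(deltas), design, covariates=("age",), min_pairs=4)
        b = fit_cpg_models(_diffs(deltas + 0.07), design, covariates=("age",), min_pairs=4)
        np.testing.assert_allclose(b["alpha"], a["alpha"] + 0.07, atol=1e-12)

    def test_pairs_with_missing_smoking_excluded(self):
        smoking = [1.0, 0.0, np.nan, 1.0, 0.0, np.nan, 1.0, 0.0]
        design = _design(8, smoking=smoking)
        deltas = np.linspace(-0.1, 0.1, 8)
        table = fit_cpg_models(_diffs(deltas), design, covariates=("smoking",), min_pairs=3)
        assert table["n_pairs_used"].iloc[0] == 6

    def test_min_pairs_guard_skips_probe(self):
        deltas = np.array([[0.1, 0.2, np.nan, np.nan, np.nan, np.nan]])
        table = fit_cpg_models(_diffs(deltas), _design(6), covariates=(), min_pairs=5)
        assert np.isnan(table["alpha"].iloc[0])
        assert table["n_pairs_used"].iloc[0] == 2

    def test_constant_covariate_column_dropped(self):
        design = _design(8, dmard=[1] * 8)  # all pairs treated
        deltas = np.random.default_rng(14).normal(0, 0.05, 8)
        table = fit_cpg_models(_diffs(deltas), design, covariates=("dmard",), min_pairs=4)
        assert np.isnan(table["dmard_slope"].iloc[0])
        assert np.isfinite(table["alpha"].iloc[0])


class TestCallDmps:
    def test_bh_matches_hand_computation(self):
        stats_table = pd.DataFrame(
            {"alpha_p": [0.01, 0.02, 0.03, 0.04]}, index=[f"cg{i}" for i in range(4)]
        )
        out = call_dmps(stats_table)
        # min over tails of p * m / rank: every probe adjusts to 0.04
        np.testing.assert_allclose(out["fdr"], [0.04, 0.04, 0.04, 0.04])

    def test_all_p_one_nothing_called(self):
        out = call_dmps(pd.DataFrame({"alpha_p": [1.0, 1.0, 1.0]}))
        assert not out["significant"].any() and not out["suggestive"].any()

    def test_single_probe_suggestive(self):
        out = call_dmps(pd.DataFrame({"alpha_p": [4e-5]}))
        assert bool(out["suggestive"].iloc[0])
        assert out["fdr"].iloc[0] == pytest.approx(4e-5)

    def test_bh_bounded_below_by_raw_and_monotone(self):
        rng = np.random.default_rng(15)
        p = rng.random(200)
        out = call_dmps(pd.DataFrame({"alpha_p": p}))
        assert (out["fdr"] >= out["alpha_p"] - 1e-15).all()
        ranked = out.sort_values("alpha_p")
        assert (np.diff(ranked["fdr"]) >= -1e-15).all()


class TestFoldChange:
    def test_fold_change_ratio_of_group_means(self, small_design):
        values = np.tile([0.6, 0.4], (1, 4))  # cases 0.6, controls 0.4
        betas = BetaMatrix(["cg0"], ["c1", "k1", "c2", "k2", "c3", "k3", "c4", "k4"], values)
        fc = fold_changes(betas, small_design)
        assert fc.iloc[0] == pytest.approx(1.5)


class TestSurfaceProjector:
    def test_projector_reproduces_fitted_coefficients(self):
        rng = np.random.default_rng(16)
        design = _design(10)
        deltas = rng.normal(0, 0.05, size=(30, 10))
        deltas[5, 3] = np.nan  # one incomplete probe
        diffs = _diffs(deltas)
        covs = ("smoking", "accp")
        table = fit_cpg_models(diffs, design, covariates=covs, min_pairs=5)
        for coef, col in (("alpha", "alpha"), ("smoking", "smoking_slope")):
            proj = build_projector(diffs, design, coef, covs, min_pairs=5)
            np.testing.assert_allclose(proj.surface(), table[col].to_numpy(), atol=1e-12)

    def test_sign_flip_equals_refit_on_flipped_deltas(self):
        rng = np.random.default_rng(17)
        design = _design(8)
        deltas = rng.normal(0, 0.05, size=(20, 8))
        diffs = _diffs(deltas)
        signs = rng.choice([1.0, -1.0], 8)
        proj = build_projector(diffs, design, "alpha", ("accp",), min_pairs=4)
        refit = fit_cpg_models(_diffs(deltas * signs), design, covariates=("accp",), min_pairs=4)
        np.testing.assert_allclose(proj.surface(signs), refit["alpha"].to_numpy(), atol=1e-12)
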