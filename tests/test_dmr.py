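import itertools

import numpy as np
import pandas as pd
import pytest

from twindmr.core_io import PairDesign, ProbeManifest
from twindmr.dmr import (
    DMRConfig,
    build_smoother,
    cluster_probes,
    compute_thresholds,
    covariate_dmrs,
    detect_bumps,
    permutation_inference,
)
from twindmr.synthetic import SpikeSpec, generate_dataset, generate_manifest, generate_pairs

from oracles import naive_bump_areas, naive_loess_smooth


def _manifest(positions, chrom="chr1"):
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(positions))],
                "chrom": [chrom] * len(positions),
                "pos": positions,
            }
        )
    )


def _probe_table(positions, cluster=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(n)],
            "chrom": ["chr1"] * n,
            "pos": positions,
            "cluster": cluster if cluster is not None else [0] * n,
        }
    )


class TestClusterProbes:
    def test_gap_rule(self):
        out = cluster_probes(_manifest([100, 400, 2000]), maxgap=500)
        assert out["cluster"].tolist() == [0, 0, 1]

    def test_singleton_chromosome(self):
        out = cluster_probes(_manifest([12345]))
        assert out["cluster"].tolist() == [0]

    def test_gap_exactly_maxgap_joins(self):
        out = cluster_probes(_manifest([100, 600, 1100]), maxgap=500)
        assert out["cluster"].nunique() == 1

    def test_chromosome_break_always_splits(self):
        table = pd.DataFrame(
            {
                "probe_id": ["cg0", "cg1"],
                "chrom": ["chr1", "chr2"],
                "pos": [100, 150],
            }
        )
        out = cluster_probes(ProbeManifest(table), maxgap=500)
        assert out["cluster"].nunique() == 2


class TestSmoother:
    def test_reproduces_constants(self):
        pos = np.arange(10) * 100
        S = build_smoother(pos, np.zeros(10, dtype=int))
        np.testing.assert_allclose(S @ np.full(10, 0.37), 0.37, atol=1e-12)

    def test_local_linear_exact_on_linear_trend(self):
        pos = np.arange(12) * 150
        S = build_smoother(pos, np.zeros(12, dtype=int), bandwidth=1000)
        values = 0.001 * pos + 0.05
        np.testing.assert_allclose(S @ values, values, atol=1e-10)

    def test_singleton_passthrough(self):
        S = build_smoother(np.array([5000]), np.array([3]))
        np.testing.assert_allclose(S @ np.array([0.42]), [0.42])

    def test_small_cluster_running_mean_window_three(self):
        pos = np.arange(4) * 100
        S = build_smoother(pos, np.zeros(4, dtype=int), min_probes_loess=7)
        values = np.array([0.0, 0.3, 0.6, 0.9])
        expected = np.array([0.15, 0.3, 0.6, 0.75])
        np.testing.assert_allclose(S @ values, expected, atol=1e-12)


class TestThresholds:
    def test_symmetric_quantile_oracle(self):
        values = np.concatenate([np.arange(1.0, 101.0), -np.arange(1.0, 101.0)])
        upper, lower = compute_thresholds(values, 0.99)
        oracle = np.quantile(np.abs(values), 0.99)  # 99.01 by linear interpolation
        assert upper == pytest.approx(oracle) == pytest.approx(99.01)
        assert lower == pytest.approx(-upper)

    def test_single_outlier_dominates_tail(self):
        values = np.zeros(1000)
        values[500] = 5.0
        upper, _ = compute_thresholds(values, 0.99)
        assert 0 <= upper < 5.0

    def test_degenerate_identical_values_warn(self, caplog):
        with caplog.at_level("WARNING"):
            upper, lower = compute_thresholds(np.full(200, 0.2))
        assert upper == pytest.approx(0.2) and lower == pytest.approx(-0.2)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_signed_mode_uses_both_tails(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.1, 1.0, 5000)
        upper, lower = compute_thresholds(values, 0.99, symmetric=False)
        assert upper == pytest.approx(np.quantile(values, 0.99))
        assert lower == pytest.approx(np.quantile(values, 0.01))


class TestDetectBumps:
    def test_run_detection_and_area(self):
        smoothed = np.array([0.0, 0.0, 0.2, 0.3, 0.2, 0.0])
        bumps = detect_bumps(smoothed, _probe_table(np.arange(6) * 100), (0.1, -0.1))
        assert len(bumps) == 1
        b = bumps.iloc[0]
        assert b["direction"] == "hyper" and b["n_probes"] == 3
        assert b["area"] == pytest.approx(0.7)
        assert (b["start"], b["end"]) == (200, 400)

    def test_opposite_signs_never_merge(self):
        bumps = detect_bumps(np.array([-0.3, 0.3]), _probe_table([100, 200]), (0.1, -0.1))
        assert len(bumps) == 2
        assert set(bumps["direction"]) == {"hyper", "hypo"}

    def test_nothing_beyond_thresholds(self):
        bumps = detect_bumps(np.zeros(5), _probe_table(np.arange(5) * 100), (0.1, -0.1))
        assert len(bumps) == 0

    def test_cluster_boundary_splits_runs(self):
        smoothed = np.array([0.3, 0.3, 0.3, 0.3])
        table = _probe_table([100, 200, 5000, 5100], cluster=[0, 0, 1, 1])
        bumps = detect_bumps(smoothed, table, (0.1, -0.1))
        assert len(bumps) == 2

    def test_area_invariant_to_probe_order_reversal(self):
        smoothed = np.array([0.0, 0.2, 0.5, 0.3, 0.0])
        table = _probe_table(np.arange(5) * 100)
        fwd = detect_bumps(smoothed, table, (0.1, -0.1))
        rev = detect_bumps(smoothed[::-1].copy(), table, (0.1, -0.1))
        assert fwd["area"].iloc[0] == pytest.approx(rev["area"].iloc[0])

    def test_bumps_never_overlap_within_surface(self):
        rng = np.random.default_rng(1)
        smoothed = rng.normal(0, 0.1, 300)
        table = _probe_table(np.arange(300) * 100, cluster=np.arange(300) // 10)
        bumps = detect_bumps(smoothed, table, (0.05, -0.05))
        spans = sorted(zip(bumps["start_idx"], bumps["end_idx"]))
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 < s2


class TestPermutationInference:
    def _tiny_dataset(self, seed=21):
        manifest = generate_manifest(n_clusters=20, probes_per_cluster=(10, 10), seed=seed)
        design = generate_pairs(n_pairs=3, missing_smoking=0.0, seed=seed + 1)
        betas, _, truth = generate_dataset(
            manifest, design, [SpikeSpec("alpha", 0.25, 5)], noise_sd=0.05, seed=seed + 2
        )
        return manifest, design, betas, truth

    def test_exhaustive_matches_naive_enumeration_oracle(self):
        """With 3 pairs the 8 sign assignments are enumerable; fwer_p must
        equal a from-scratch loess + run-scan enumeration exactly."""
        manifest, design, betas, _ = self._tiny_dataset()
        config = DMRConfig(covariates=(), min_pairs=3, n_perm=8)
        result = permutation_inference(
            betas, design, manifest, "alpha", config, exhaustive=True
        )
        assert len(result) > 0

        from twindmr.pairmodel import compute_pair_differences

        delta = compute_pair_differences(betas, design).delta
        pos = manifest.table["pos"].to_numpy()
        cluster_ids = cluster_probes(manifest, 500)["cluster"].to_numpy()
        observed = naive_loess_smooth(pos, delta.mean(axis=1), cluster_ids)
        upper = float(np.quantile(np.abs(observed), 0.99))
        obs_areas = sorted(naive_bump_areas(observed, cluster_ids, upper, -upper), reverse=True)
        max_areas = []
        for signs in itertools.product([1.0, -1.0], repeat=3):
            surface = (delta * np.array(signs)).mean(axis=1)
            smoothed = naive_loess_smooth(pos, surface, cluster_ids)
            areas = naive_bump_areas(smoothed, cluster_ids, upper, -upper)
            max_areas.append(max(areas) if areas else 0.0)
        np.testing.assert_allclose(result["area"].to_numpy(), obs_areas, rtol=1e-9)
        expected_fwer = [np.mean([m > a for m in max_areas]) for a in obs_areas]
        np.testing.assert_allclose(result["fwer_p"].to_numpy(), expected_fwer, atol=1e-12)

    def test_pvalues_live_on_permutation_grid(self):
        manifest, design, betas, _ = self._tiny_dataset(seed=31)
        config = DMRConfig(covariates=(), min_pairs=3, n_perm=50)
        result = permutation_inference(betas, design, manifest, "alpha", config, seed=5)
        grid = np.round(result["fwer_p"] * 50)
        np.testing.assert_allclose(result["fwer_p"] * 50, grid, atol=1e-9)
        assert result["fwer_p"].between(0, 1).all()
        assert result["emp_p"].between(0, 1).all()

    def test_dominant_spike_hits_fwer_boundary(self):
        manifest = generate_manifest(n_clusters=50, seed=41)
        design = generate_pairs(seed=42)
        betas, _, truth = generate_dataset(
            manifest, design, [SpikeSpec("alpha", 0.3, 10)], noise_sd=0.02, seed=43
        )
        config = DMRConfig(covariates=(), min_pairs=10, n_perm=100)
        result = permutation_inference(betas, design, manifest, "alpha", config, seed=44)
        top = result.iloc[0]
        assert top["fwer_p"] == 0.0 and bool(top["fwer_boundary"])
        region = truth.regions.iloc[0]
        assert top["start"] <= region["end"] and top["end"] >= region["start"]

    def test_deterministic_given_seed(self):
        manifest, design, betas, _ = self._tiny_dataset(seed=51)
        config = DMRConfig(covariates=(), min_pairs=3, n_perm=30)
        a = permutation_inference(betas, design, manifest, "alpha", config, seed=9)
        b = permutation_inference(betas, design, manifest, "alpha", config, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCovariateDmrs:
    def test_constant_covariate_surface_skipped(self, caplog):
        manifest = generate_manifest(n_clusters=30, seed=61)
        design = generate_pairs(seed=62)
        design.table["accp"] = 0  # nobody anti-CCP positive
        betas, _, _ = generate_dataset(manifest, design, seed=63)
        config = DMRConfig(covariates=("smoking", "accp", "dmard"), n_perm=10)
        with caplog.at_level("WARNING"):
            tables = covariate_dmrs(betas, design, manifest, ("alpha", "accp"), config, seed=64)
        assert "accp" not in tables and "alpha" in tables

    def test_smoking_spike_tops_smoking_surface(self):
        manifest = generate_manifest(n_clusters=100, seed=71)
        design = generate_pairs(seed=72)
        betas, _, truth = generate_dataset(
            manifest, design, [SpikeSpec("smoking", 0.25, 10)], noise_sd=0.04, seed=73
        )
        config = DMRConfig(n_perm=50)
        tables = covariate_dmrs(betas, design, manifest, ("smoking",), config, seed=74)
        top = tables["smoking"].iloc[0]
        region = truth.regions.iloc[0]
        assert top["start"] <= region["start"] and top["end"] >= region["end"] - 1
        assert "fold_change" in tables["smoking"].columns
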