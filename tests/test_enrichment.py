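"""Upstream kinase inference: resampling null, z/Δ-confidence, MEOW, scores."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import adipokinome as ak
from adipokinome.enrichment import (
    enumerate_null,
    krsa_zscore,
    meow_score,
    sample_null,
    significance_score,
    specificity_score,
)
from adipokinome.errors import SizingError, ValidationError
from adipokinome.mapping import KinaseSubstrateMap, read_map, write_map


def _map(entries, universe):
    return KinaseSubstrateMap(
        {k: tuple(v) for k, v in entries.items()}, frozenset(universe)
    )


class TestMapIO:
    def test_rank_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("kinase,peptide_id,rank\nK,p1,0\nK,p2,5\nK,p3,13\n")
        with pytest.raises(ValidationError):
            read_map(p)

    def test_rank_cutoff_inclusive(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("kinase,peptide_id,rank\nK,p1,0\nK,p2,4\nK,p3,5\n")
        kmap = read_map(p, rank_max=4, min_substrates=0)
        assert set(kmap.substrates("K")) == {"p1", "p2"}

    def test_round_trip_preserves_map(self, tmp_path, small_map):
        p = tmp_path / "map.csv"
        write_map(small_map, p)
        back = read_map(p, universe=small_map.universe)
        assert back.entries == small_map.entries
        assert back.universe == small_map.universe

    def test_undercovered_kinases_dropped(self, tmp_path):
        p = tmp_path / "map.csv"
        p.write_text("kinase,peptide_id,rank\nA,p1,0\nA,p2,0\nA,p3,0\nB,p1,0\n")
        kmap = read_map(p, min_substrates=3)
        assert set(kmap.entries) == {"A"}


class TestObservedHits:
    def test_set_intersection(self):
        kmap = _map({"K": [("a", 0), ("b", 0), ("c", 0)]}, "abcd")
        assert ak.observed_hits({"b", "c", "d"}, kmap, "K") == 2
        assert ak.observed_hits(set(), kmap, "K") == 0

    def test_unknown_kinase_raises(self):
        kmap = _map({"K": [("a", 0)]}, "a")
        with pytest.raises(KeyError):
            ak.observed_hits({"a"}, kmap, "X")

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        universe = [f"p{i}" for i in range(40)]
        entries = {
            f"K{j}": [(p, 0) for p in rng.choice(universe, size=8, replace=False)]
            for j in range(6)
        }
        kmap = _map(entries, universe)
        diff = set(rng.choice(universe, size=15, replace=False))
        for k, subs in entries.items():
            brute = sum(1 for p, _ in subs for d in [p] if d in diff)
            assert ak.observed_hits(diff, kmap, k) == brute


class TestSampleNull:
    def test_moments_match_hypergeometric_within_4se(self):
        """Uniform draws without replacement => hypergeometric hit counts."""
        rng = np.random.default_rng(3)
        universe = [f"p{i}" for i in range(100)]
        entries = {
            f"K{j:02d}": [(p, 0) for p in rng.choice(universe, 5 + 2 * j, replace=False)]
            for j in range(8)
        }
        null = sample_null(_map(entries, universe), n_differential=20,
                           n_iterations=2000, seed=99)
        P, D, N = 100, 20, 2000
        for ki, m in enumerate(null.m):
            hyper = stats.hypergeom(P, m, D)
            se_mean = hyper.std() / math.sqrt(N)
            assert abs(null.mean[ki] - hyper.mean()) < 4 * se_mean
            se_sd = hyper.std() / math.sqrt(2 * (N - 1))
            assert abs(null.sd[ki] - hyper.std()) < 4 * se_sd

    def test_exhaustive_draw_is_deterministic(self):
        kmap = _map({"K": [("a", 0), ("b", 0)]}, "abcde")
        null = sample_null(kmap, n_differential=5, n_iterations=100, seed=1)
        assert null.mean[0] == 2.0 and null.sd[0] == 0.0

    def test_oversized_draw_rejected(self):
        kmap = _map({"K": [("a", 0)]}, "ab")
        with pytest.raises(SizingError):
            sample_null(kmap, n_differential=3)

    def test_seeded_reproducibility(self):
        kmap = _map({"K": [("a", 0), ("b", 0), ("c", 0)]}, "abcdefgh")
        a = sample_null(kmap, 4, n_iterations=50, seed=5)
        b = sample_null(kmap, 4, n_iterations=50, seed=5)
        np.testing.assert_array_equal(a.hits, b.hits)

    def test_small_universe_agrees_with_exact_enumeration(self):
        """For P <= 12 all C(P, D) draws are enumerable as an exact oracle."""
        rng = np.random.default_rng(8)
        universe = [f"p{i}" for i in range(10)]
        entries = {
            "A": [(p, 0) for p in universe[:4]],
            "B": [(p, 0) for p in universe[2:9]],
        }
        kmap = _map(entries, universe)
        exact = enumerate_null(kmap, n_differential=4).set_index("kinase")
        # enumeration equals the closed form exactly
        for k, m in (("A", 4), ("B", 7)):
            hyper = stats.hypergeom(10, m, 4)
            assert exact.loc[k, "null_mean"] == pytest.approx(hyper.mean(), abs=1e-12)
        sampled = sample_null(kmap, 4, n_iterations=4000, seed=2)
        for ki, k in enumerate(sampled.kinases):
            se = exact.loc[k, "null_sd"] / math.sqrt(4000)
            assert abs(sampled.mean[ki] - exact.loc[k, "null_mean"]) < 4 * se


class TestScores:
    def test_zscore_and_delta_confidence_formulas(self):
        z, delta = krsa_zscore(6.0, 2.0, 1.206)
        assert z == pytest.approx((6 - 2) / 1.206)
        assert delta == pytest.approx(3.0)
        assert krsa_zscore(2.0, 2.0, 1.0)[0] == pytest.approx(0.0)
        z0, d0 = krsa_zscore(3.0, 0.0, 0.0)
        assert np.isnan(z0) and np.isnan(d0)

    def test_kinase_statistic_is_median_of_all_substrates(self):
        assert ak.kinase_statistic([0.5, 0.6, 0.7]) == pytest.approx(0.6)
        assert ak.kinase_statistic([0.0, 0.0, 0.0]) == pytest.approx(0.0)
        assert np.isnan(ak.kinase_statistic([0.5, 0.6]))  # below coverage

    def test_specificity_caps_at_continuity_limit(self):
        null = np.zeros(2000, dtype=int)
        assert specificity_score(5, null) == pytest.approx(-math.log10(1 / 2001))
        assert specificity_score(0, null) == pytest.approx(0.0, abs=1e-12)

    def test_significance_score_zero_for_null_substrates(self):
        rng = np.random.default_rng(0)
        assert significance_score(np.zeros(8), rng=rng) == pytest.approx(0.0, abs=1e-9)

    def test_meow_formula_and_sign_propagation(self):
        meow, terms = meow_score(np.array([0.4, 0.5, 0.6]), 3.0)
        assert meow == pytest.approx(0.5 * 3.0)
        np.testing.assert_allclose(terms, [1.2, 1.5, 1.8])
        neutral, _ = meow_score(np.array([0.25, 0.75]), 1.0)
        assert neutral == pytest.approx(0.5)
        hypo, _ = meow_score(np.array([-0.5, -0.7]), 2.0)
        assert hypo < 0
        undef, _ = meow_score(np.array([]), 2.0)
        assert np.isnan(undef)

    def test_meow_sign_matches_mean_differential_log2fc_sign(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vals = rng.normal(0, 1, size=rng.integers(1, 9))
            delta = float(rng.uniform(0.1, 5.0))
            meow, _ = meow_score(vals, delta)
            assert np.sign(meow) == np.sign(np.mean(vals))


class TestScoreKinases:
    def test_planted_hyperactive_kinase_statistic_is_log2_multiplier(self):
        """Noise-free x2 kinase with rank-0 substrates: statistic = 1.0."""
        universe = [f"p{i}" for i in range(12)]
        kmap = _map(
            {"HOT": [(p, 0) for p in universe[:4]],
             "COLD": [(p, 0) for p in universe[4:8]]},
            universe,
        )
        truth = ak.PlantedTruth(
            {"HOT": 2.0, "COLD": 1.0}, {p: 20.0 for p in universe}, noise_cv=0.0
        )
        exp = ak.simulate_experiment(truth, kmap, seed=0)
        out = ak.analyze(exp.readings, kmap)
        scores = out["scores"].set_index("kinase")
        assert scores.loc["HOT", "kinase_statistic"] == pytest.approx(1.0, abs=1e-9)
        assert scores.loc["COLD", "kinase_statistic"] == pytest.approx(0.0, abs=1e-9)
        assert scores.loc["HOT", "observed_hits"] == 4
        assert scores.loc["HOT", "z"] > scores.loc["COLD", "z"]

    def test_scoring_is_deterministic_under_seed(self, small_map):
        rng = np.random.default_rng(1)
        peps = sorted(small_map.universe)
        rec = pd.DataFrame({
            "peptide_id": peps,
            "mean_fc": rng.uniform(0.5, 2.0, len(peps)),
        })
        rec["log2_fc"] = np.log2(rec.mean_fc)
        rec, _ = ak.classify_differential(rec)
        a = ak.score_kinases(rec, small_map, n_iterations=300, seed=7)
        b = ak.score_kinases(rec, small_map, n_iterations=300, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_final_score_separates_planted_from_null_kinases(self):
        """Across seeds, planted kinases outrank null ones by final score."""
        wins = 0
        n = 10
        for seed in range(n):
            exp, planted = ak.planted_experiment(
                seed=seed, n_kinases=20, n_peptides=80, n_planted=2
            )
            out = ak.analyze(
                exp.readings, exp.map,
                config=ak.PipelineConfig(seed=seed, n_iterations=500),
            )
            s = out["scores"]
            planted_min = s.loc[s.kinase.isin(planted), "final_score"].min()
            null_med = s.loc[~s.kinase.isin(planted), "final_score"].median()
            wins += planted_min > null_med
        assert wins >= int(0.9 * n)
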