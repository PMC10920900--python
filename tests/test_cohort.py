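"""Permutation, hypergeometric, overrepresentation, and benchmarking stats."""

import numpy as np
import pandas as pd
import pytest

from oracles import hypergeom_lower_oracle
from splicefate.cohort import (
    HypergeomParams,
    benchmark_scores,
    build_survival_groups,
    deleterious_rate_test,
    driver_enrichment,
    gene_counts,
    hypergeometric_lower_tail,
    match_mutation_volume,
    permutation_depletion,
    rank_overrepresented_genes,
)
from splicefate.errors import InputError


class TestPermutationDepletion:
    def test_null_mean_matches_analytic_expectation(self):
        r = permutation_depletion(10_000, 1_000, 500, 30, iterations=10_000, seed=1)
        analytic = 500 * 1_000 / 10_000
        se = np.sqrt(500 * 0.1 * 0.9 * (9_500 / 9_999) / 10_000)
        assert abs(r.null_mean - analytic) < 3 * se

    def test_fully_flagged_pool_gives_p_one(self):
        r = permutation_depletion(100, 100, 40, 40, iterations=200, seed=0)
        assert r.p_value == 1.0

    def test_depleted_observation_hits_the_floor(self):
        r = permutation_depletion(10_000, 5_000, 200, 0, iterations=500, seed=0)
        assert r.p_value <= 1 / 500
        assert r.p_display == "<1/500"

    def test_reproducible_given_seed(self):
        a = permutation_depletion(1000, 100, 50, 3, iterations=300, seed=9)
        b = permutation_depletion(1000, 100, 50, 3, iterations=300, seed=9)
        assert a.null_mean == b.null_mean and a.n_extreme == b.n_extreme

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(InputError):
            permutation_depletion(10, 5, 20, 1)
        with pytest.raises(InputError):
            permutation_depletion(10, 5, 5, 9)

    def test_null_calibration_super_uniform(self):
        """p-values under the null: at most ~5% fall below 0.05."""
        rng = np.random.default_rng(17)
        low = 0
        reps = 200
        for i in range(reps):
            observed = int(rng.hypergeometric(800, 9200, 400))
            r = permutation_depletion(10_000, 800, 400, observed,
                                      iterations=200, seed=int(rng.integers(2**31)))
            low += r.p_value < 0.05
        assert low / reps <= 0.07


class TestHypergeometric:
    def test_printed_example(self):
        p = hypergeometric_lower_tail(HypergeomParams(10, 5, 4, 1))
        assert p == pytest.approx(55 / 210)

    def test_full_support_is_one(self):
        assert hypergeometric_lower_tail(HypergeomParams(10, 5, 4, 4)) == 1.0
        assert hypergeometric_lower_tail(HypergeomParams(10, 0, 4, 0)) == 1.0

    def test_matches_exhaustive_enumeration_small(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = hypergeometric_lower_tail(HypergeomParams(N, K, n, k))
                        assert got == pytest.approx(
                            hypergeom_lower_oracle(N, K, n, k), abs=1e-12)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(InputError):
            HypergeomParams(10, 5, 4, 5)


class TestDeleteriousRate:
    def test_identical_ratios_give_p_one(self):
        ratios = {f"g{i}": 0.3 for i in range(50)}
        r = deleterious_rate_test(ratios, {"g0", "g1"}, iterations=300, seed=0)
        assert r.p_value == 1.0

    def test_top_ratio_targets_hit_floor(self):
        ratios = {f"g{i}": i / 100 for i in range(100)}
        r = deleterious_rate_test(ratios, {"g97", "g98", "g99"},
                                  iterations=2000, seed=3)
        assert r.p_value <= 1 / 1000

    def test_target_equals_universe(self):
        ratios = {f"g{i}": i / 10 for i in range(10)}
        r = deleterious_rate_test(ratios, set(ratios), iterations=200, seed=0)
        assert r.p_value == 1.0
        assert r.observed == pytest.approx(r.null_mean)

    def test_empty_target_rejected(self):
        with pytest.raises(InputError):
            deleterious_rate_test({"g": 0.1}, set())


def _counts(n=100, volumes=None, dels=None):
    volumes = volumes if volumes is not None else np.full(n, 50)
    dels = dels if dels is not None else np.zeros(n, dtype=int)
    return pd.DataFrame({
        "gene": [f"g{i:03d}" for i in range(n)],
        "N_unique": volumes,
        "N_mis": np.maximum(dels, 5),
        "N_del": dels,
    })


class TestOverrepresentation:
    def test_uniform_volumes_top5_selects_one_per_bin(self):
        dels = np.zeros(100, dtype=int)
        dels[[3, 23, 43, 63, 83]] = 5  # one standout per volume bin
        sel = rank_overrepresented_genes(gene_counts(_counts(dels=dels)))
        assert len(sel) == 5

    def test_zero_ratio_never_beats_positive_binmate(self):
        rng = np.random.default_rng(8)
        dels = rng.integers(0, 3, size=100)
        counts = gene_counts(_counts(dels=dels))
        sel = rank_overrepresented_genes(counts, top_percent=0.10)
        for _, grp in counts.groupby("bin"):
            chosen = grp[grp["gene"].isin(sel)]
            unchosen = grp[~grp["gene"].isin(sel)]
            if (chosen["R_del"] == 0).any():
                assert (unchosen["R_del"] == 0).all()

    def test_equal_volumes_match_global_sort_oracle(self):
        """With equal volumes and one standout per bin, binned selection
        equals a plain global top-5% sort (independent oracle)."""
        dels = np.zeros(100, dtype=int)
        standouts = [3, 23, 43, 63, 83]
        for rank, i in enumerate(standouts):
            dels[i] = 20 - rank
        counts = gene_counts(_counts(dels=dels))
        sel = rank_overrepresented_genes(counts, top_percent=0.05)
        oracle = set(
            counts.sort_values(["R_del", "gene"], ascending=[False, True])
            ["gene"].head(5)
        )
        assert sel == oracle == {f"g{i:03d}" for i in standouts}

    def test_invalid_counts_rejected(self):
        df = _counts()
        df.loc[0, "N_unique"] = 0
        with pytest.raises(InputError):
            gene_counts(df)


class TestDriverEnrichment:
    def test_drivers_equal_universe(self):
        universe = {f"g{i}" for i in range(50)}
        sel = {f"g{i}" for i in range(10)}
        overlap, perm, _ = driver_enrichment(sel, universe, universe,
                                             iterations=200, seed=0)
        assert overlap == len(sel)
        assert perm.p_value == 1.0

    def test_disjoint_selection_p_near_one(self):
        universe = {f"g{i}" for i in range(200)}
        drivers = {f"g{i}" for i in range(100)}
        sel = {f"g{i}" for i in range(150, 190)}
        _, perm, _ = driver_enrichment(sel, drivers, universe,
                                       iterations=400, seed=0)
        assert perm.p_value > 0.99

    def test_null_mean_tracks_analytic_value(self):
        universe = {f"g{i}" for i in range(1000)}
        drivers = {f"g{i}" for i in range(100)}
        sel = {f"g{i}" for i in range(500, 550)}
        _, perm, _ = driver_enrichment(sel, drivers, universe,
                                       iterations=2000, seed=5)
        assert perm.null_mean == pytest.approx(50 * 0.1, abs=0.3)


class TestBenchmark:
    def test_top_cut_ppv(self):
        curves = benchmark_scores({"a": 3, "b": 2, "c": 1},
                                  {"a": "pathogenic", "b": "benign",
                                   "c": "pathogenic"},
                                  percentiles=np.array([67]))
        assert curves.ppv_by_percentile[0][1] == 1.0

    def test_perfect_separation_auc(self):
        scores = {f"v{i}": float(i) for i in range(20)}
        labels = {f"v{i}": "pathogenic" if i >= 10 else "benign" for i in range(20)}
        assert benchmark_scores(scores, labels).auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(21)
        aucs = []
        for _ in range(30):
            scores = {f"v{i}": float(rng.random()) for i in range(200)}
            labels = {f"v{i}": "pathogenic" if i < 100 else "benign"
                      for i in range(200)}
            aucs.append(benchmark_scores(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_ambiguous_excluded_and_all_ambiguous_rejected(self):
        curves = benchmark_scores(
            {"a": 3, "b": 2, "c": 1},
            {"a": "pathogenic", "b": "ambiguous", "c": "benign"},
            percentiles=np.array([50]))
        assert curves.ppv_by_percentile[0][1] == 1.0
        with pytest.raises(InputError):
            benchmark_scores({"a": 1.0}, {"a": "ambiguous"})


class TestSurvivalGroups:
    def test_group_rules(self):
        df = pd.DataFrame({
            "patient_id": ["p1", "p1", "p2", "p3", "p4"],
            "gene": ["g1", "g2", "g1", "g1", "g9"],
            "is_missplicing": [True, False, True, False, True],
            "is_deleterious": [True, False, False, False, True],
        })
        groups = build_survival_groups(df, {"g1", "g2"})
        got = dict(zip(groups["patient_id"], groups["group"]))
        # p1 affected (deleterious in set); p2 excluded (missplicing, not
        # deleterious); p3 and p4 unaffected (no missplicing in set)
        assert got == {"p1": "affected", "p3": "unaffected", "p4": "unaffected"}

    def test_volume_matching_restricts_band(self):
        groups = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(10)],
            "group": ["affected"] * 5 + ["unaffected"] * 5,
        })
        volumes = {f"p{i}": i * 10 for i in range(10)}
        banded = match_mutation_volume(groups, volumes, 20, 80)
        vols = [volumes[p] for p in banded["patient_id"]]
        assert min(vols) >= np.percentile(list(volumes.values()), 20)
        assert max(vols) <= np.percentile(list(volumes.values()), 80)
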