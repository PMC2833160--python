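"""Cluster calling, threshold calibration, positional enrichment and
terminal-range counts."""

import numpy as np
import pytest

from rarecodon.clusters import (
    ClusterCallSet,
    _intervals_from_flags,
    calibrate_threshold,
    call_clusters,
    call_orfeome_clusters,
    classify_terminal_genes,
    null_cluster_sets,
    positional_profile,
)
from rarecodon.minmax import MinMaxProfile, score_orfeome
from rarecodon.nulls import randomize_orfeome


def profile_of(values):
    return MinMaxProfile("g", 18, np.asarray(values, dtype=float))


class TestCallClusters:
    @pytest.mark.parametrize(
        "values,intervals",
        [
            ([-12, -5, 3], [(1, 1)]),
            ([-9.9, 5, 0], []),
            ([-11, -11, -4, -15], [(1, 2), (4, 4)]),
            ([-10, -10, -10], [(1, 3)]),  # threshold is inclusive
        ],
    )
    def test_interval_examples(self, values, intervals):
        assert call_clusters(profile_of(values)).intervals == intervals

    def test_masked_windows_never_flagged(self):
        cs = call_clusters(profile_of([np.nan, -50, np.nan]))
        assert cs.intervals == [(2, 2)]
        assert not cs.flags[0] and not cs.flags[2]

    def test_nonnegative_tau_rejected(self):
        with pytest.raises(ValueError):
            call_clusters(profile_of([-12]), tau=5)

    def test_flags_match_definition(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        profiles = score_orfeome(orfeome, truth.usage_table)
        for p, cs in zip(profiles, call_orfeome_clusters(profiles)):
            expected = np.where(np.isnan(p.values), False, p.values <= -10)
            np.testing.assert_array_equal(cs.flags, expected)


class TestThresholdCalibration:
    def test_planted_excess_returns_default_tau(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        cal = calibrate_threshold(orfeome, truth.usage_table, null_reps=8, seed=1)
        assert cal.tau == -10.0 and cal.significant

    def test_null_orfeome_not_significant(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        null = randomize_orfeome(orfeome, "weighted", 1, seed=4, table=truth.usage_table)[0]
        cal = calibrate_threshold(null, truth.usage_table, null_reps=8, seed=1)
        assert not cal.significant
        assert cal.tau == -10.0  # default applied

    def test_empty_candidates_error(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        with pytest.raises(ValueError):
            calibrate_threshold(orfeome, truth.usage_table, candidate_taus=())


def truth_call_sets(n_genes, n_windows, flagged):
    """Build ClusterCallSets directly from planted window positions."""
    sets = []
    for g in range(n_genes):
        flags = np.zeros(n_windows, dtype=bool)
        for w in flagged.get(g, []):
            flags[w - 1] = True
        sets.append(ClusterCallSet(f"g{g}", -10.0, flags, _intervals_from_flags(flags)))
    return sets


class TestClassifyTerminal:
    def test_window_30_counts_in_first50_not_first25(self):
        sets = truth_call_sets(1, 300, {0: [30]})
        df = classify_terminal_genes(sets).set_index(["side", "range"])
        assert df.loc[("5prime", "first_50"), "n_genes_with_cluster"] == 1
        assert df.loc[("5prime", "first_25"), "n_genes_with_cluster"] == 0

    def test_final_window_counts_in_all_3prime_ranges(self):
        sets = truth_call_sets(1, 300, {0: [300]})
        df = classify_terminal_genes(sets).set_index(["side", "range"])
        for rng_name in ("terminal_1", "first_25", "first_50"):
            assert df.loc[("3prime", rng_name), "n_genes_with_cluster"] == 1
        assert df.loc[("5prime", "terminal_1"), "n_genes_with_cluster"] == 0

    def test_counts_equal_planted_truth_exactly(self, rng):
        planted = {}
        for g in range(200):
            k = rng.integers(0, 4)
            planted[g] = sorted(set(rng.integers(1, 301, size=k).tolist()))
        sets = truth_call_sets(200, 300, planted)
        df = classify_terminal_genes(sets).set_index(["side", "range"])
        expect_first50 = sum(1 for ws in planted.values() if any(w <= 50 for w in ws))
        expect_last25 = sum(1 for ws in planted.values() if any(w > 275 for w in ws))
        assert df.loc[("5prime", "first_50"), "n_genes_with_cluster"] == expect_first50
        assert df.loc[("3prime", "first_25"), "n_genes_with_cluster"] == expect_last25

    def test_range_nesting_is_monotone(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        sets = call_orfeome_clusters(score_orfeome(orfeome, truth.usage_table))
        df = classify_terminal_genes(sets).set_index(["side", "range"])
        for side in ("5prime", "3prime"):
            c1 = df.loc[(side, "terminal_1"), "n_genes_with_cluster"]
            c25 = df.loc[(side, "first_25"), "n_genes_with_cluster"]
            c50 = df.loc[(side, "first_50"), "n_genes_with_cluster"]
            assert c1 <= c25 <= c50


class TestPositionalProfile:
    def test_pct_matches_brute_force_recount(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        sets = call_orfeome_clusters(score_orfeome(orfeome, truth.usage_table))
        prof = positional_profile(sets, "5prime", 100, [])
        for pos in (1, 10, 60):
            manual = 100.0 * sum(cs.flags[pos - 1] for cs in sets) / len(sets)
            assert prof.pct_genes[pos - 1] == pytest.approx(manual)

    def test_3prime_indexes_from_final_window(self):
        sets = truth_call_sets(4, 260, {0: [260], 1: [1]})
        prof = positional_profile(sets, "3prime", 10, [])
        assert prof.pct_genes[0] == pytest.approx(25.0)  # only gene 0
        assert (prof.pct_genes[1:] == 0).all()

    def test_self_null_z_near_zero(self, small_synthetic):
        """Feeding null replicates as both observed and null keeps |z| < 3
        nearly everywhere."""
        _, orfeome, truth = small_synthetic
        nulls = null_cluster_sets(orfeome, truth.usage_table, 12, seed=77, tau=-10)
        prof = positional_profile(nulls[0], "5prime", 200, nulls[1:])
        finite = prof.z[np.isfinite(prof.z)]
        assert (np.abs(finite) < 3).mean() >= 0.99 if len(finite) else True

    def test_max_pos_beyond_shortest_gene_errors(self, small_synthetic):
        _, orfeome, truth = small_synthetic
        sets = call_orfeome_clusters(score_orfeome(orfeome, truth.usage_table))
        shortest = min(len(cs) for cs in sets)
        with pytest.raises(ValueError, match="max_pos"):
            positional_profile(sets, "5prime", shortest + 1, [])

    def test_bad_orientation_errors(self):
        sets = truth_call_sets(2, 260, {})
        with pytest.raises(ValueError, match="orientation"):
            positional_profile(sets, "sideways", 10, [])
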