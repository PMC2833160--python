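"""%MinMax window statistic: extremes, oracle equivalence, invariances."""

import numpy as np
import pytest

from rarecodon._codes import CODONS, synonymous_families
from rarecodon.minmax import minmax_window, score_gene, score_orfeome
from rarecodon.orfeome import ORFRecord
from rarecodon.synth import SyntheticSpec, generate_orfeome

FAMS = synonymous_families("standard")


def extreme_codon(table, aa, which):
    cs = FAMS[aa]
    key = (lambda c: table.freq[c]) if which == "max" else (lambda c: -table.freq[c])
    return max(cs, key=key)


class TestWindowExtremes:
    def test_all_most_common_is_plus_100(self, skewed_table):
        window = [extreme_codon(skewed_table, aa, "max") for aa in "LKFESGRVIT" * 2][:18]
        assert minmax_window(window, skewed_table) == pytest.approx(100.0)

    def test_all_rarest_is_minus_100(self, skewed_table):
        window = [extreme_codon(skewed_table, aa, "min") for aa in "LKFESGRVIT" * 2][:18]
        assert minmax_window(window, skewed_table) == pytest.approx(-100.0)

    def test_all_met_is_zero(self, skewed_table):
        assert minmax_window(["ATG"] * 18, skewed_table) == 0.0

    def test_uniform_table_degenerates_to_zero(self, toy_table):
        # families other than Lys/Phe are uniform: Mx = V = Mn
        assert minmax_window(["GGG"] * 18, toy_table) == 0.0

    def test_unknown_codon_raises_with_name(self, toy_table):
        with pytest.raises(KeyError, match="TAA"):
            minmax_window(["TAA"] * 18, toy_table)


class TestToyOracle:
    def brute_force(self, window, table):
        A = sum(table.freq[c] for c in window)
        V = sum(table.x_avg[table.aa_of[c]] for c in window)
        Mx = sum(table.x_max[table.aa_of[c]] for c in window)
        Mn = sum(table.x_min[table.aa_of[c]] for c in window)
        if A >= V:
            return 100 * (A - V) / (Mx - V) if Mx > V else 0.0
        return -100 * (V - A) / (V - Mn) if V > Mn else 0.0

    @pytest.mark.parametrize(
        "window",
        [
            ["AAG"] * 9 + ["TTC"] * 9,
            ["AAA"] * 9 + ["TTC"] * 9,
            ["AAA"] * 9 + ["TTT"] * 9,
            ["AAG"] * 3 + ["AAA"] * 6 + ["TTC"] * 5 + ["TTT"] * 4,
        ],
    )
    def test_two_family_windows_match_hand_sums(self, toy_table, window):
        assert minmax_window(window, toy_table) == pytest.approx(
            self.brute_force(window, toy_table)
        )

    def test_rarest_two_family_window_value(self, toy_table):
        # 9xAAG + 9xTTC uses each family's least common codon: exactly -100
        assert minmax_window(["AAG"] * 9 + ["TTC"] * 9, toy_table) == pytest.approx(-100.0)


class TestScoreOrfeome:
    def test_window_count_convention(self, skewed_table):
        orf = ORFRecord("g", "AAA" * 20)
        prof = score_gene(orf, skewed_table)
        assert len(prof.values) == 2

    def test_short_gene_empty_profile(self, skewed_table):
        prof = score_gene(ORFRecord("g", "AAA" * 18), skewed_table)
        assert len(prof.values) == 0

    def test_masked_windows_are_nan(self, skewed_table):
        seq = "AAA" * 30 + "ANA" + "AAA" * 30
        prof = score_gene(ORFRecord("g", seq), skewed_table)
        # windows overlapping codon 31 (positions 14..31) are masked
        assert np.isnan(prof.values[13:31]).all()
        assert not np.isnan(prof.values[:13]).any()
        assert not np.isnan(prof.values[31:]).any()

    def test_vectorized_equals_naive_loop(self, skewed_table, rng):
        sense = [c for c in CODONS if c in skewed_table.aa_of]
        for _ in range(20):
            n = int(rng.integers(19, 120))
            seq = "".join(rng.choice(sense, n))
            orf = ORFRecord("g", seq)
            prof = score_gene(orf, skewed_table)
            codons = orf.codons
            naive = [
                minmax_window(codons[i : i + 18], skewed_table)
                for i in range(n - 18)
            ]
            np.testing.assert_allclose(prof.values, naive, rtol=0, atol=1e-9)

    def test_bounds_on_synthetic_orfeome(self, small_synthetic, skewed_table):
        _, orfeome, truth = small_synthetic
        for prof in score_orfeome(orfeome, truth.usage_table):
            vals = prof.values[~np.isnan(prof.values)]
            assert (vals >= -100 - 1e-9).all() and (vals <= 100 + 1e-9).all()

    def test_all_common_recoding_scores_plus_100_everywhere(self, skewed_table, rng):
        sense = [c for c in CODONS if c in skewed_table.aa_of]
        seq = "".join(rng.choice(sense, 60))
        orf = ORFRecord("g", seq)
        recoded = "".join(
            extreme_codon(skewed_table, skewed_table.aa_of[c], "max") for c in orf.codons
        )
        prof = score_gene(ORFRecord("g", recoded), skewed_table)
        np.testing.assert_allclose(prof.values, 100.0)


class TestMonotonicity:
    def test_commoner_synonym_never_decreases_value(self, skewed_table, rng):
        """Replacing one codon by a more common synonym is monotone in the
        window value."""
        sense = [c for c in CODONS if c in skewed_table.aa_of]
        for _ in range(300):
            window = list(rng.choice(sense, 18))
            i = int(rng.integers(18))
            aa = skewed_table.aa_of[window[i]]
            syns = sorted(FAMS[aa], key=lambda c: skewed_table.freq[c])
            j = syns.index(window[i])
            if j == len(syns) - 1:
                continue
            v0 = minmax_window(window, skewed_table)
            window[i] = syns[j + 1]
            assert minmax_window(window, skewed_table) >= v0 - 1e-12


def test_synonymy_leaves_baselines_unchanged(skewed_table, rng):
    """Synonymous recoding moves A only: V, Mx, Mn per window are functions
    of the protein, so the all-common recode of any gene hits +100 and the
    all-rare recode hits -100 at every window."""
    spec = SyntheticSpec(n_genes=3, seed=9, q5=0, q3=0, background_rate=0)
    orfeome, truth = generate_orfeome(spec)
    t = truth.usage_table
    for orf in orfeome:
        rare = "".join(extreme_codon(t, t.aa_of[c], "min") for c in orf.codons)
        prof = score_gene(ORFRecord(orf.gene_id, rare), t)
        np.testing.assert_allclose(prof.values, -100.0)
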