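"""Contingency statistics: Fisher exact, Yates chi-square, per-codon usage
tables, expression strata."""

import numpy as np
import pytest
from scipy import stats as sps

from rarecodon.orfeome import ORFRecord
from rarecodon.stats import (
    category_enrichment,
    chisq_yates,
    codon_usage_contingency,
    fisher_two_tailed,
    stratify_expression,
)


class TestFisher:
    def test_signal_sequence_5prime_table(self):
        # 172/454 signal genes vs 574/1808 without, first 50 windows
        res = fisher_two_tailed(172, 282, 574, 1234)
        assert res.p_value == pytest.approx(0.0140, abs=5e-5)

    def test_signal_sequence_3prime_table(self):
        res = fisher_two_tailed(113, 365, 424, 1515)
        assert res.p_value == pytest.approx(0.4246, abs=5e-5)

    def test_minimal_table_enumeration(self):
        # margins (1,1)x(1,1): both tables equally probable -> p = 1
        assert fisher_two_tailed(1, 0, 0, 1).p_value == pytest.approx(1.0)

    def test_degenerate_margin_returns_one(self, caplog):
        with caplog.at_level("WARNING"):
            res = fisher_two_tailed(0, 0, 5, 7)
        assert res.p_value == 1.0

    def test_symmetric_under_row_and_column_swap(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 80, 4))
            p1 = fisher_two_tailed(a, b, c, d).p_value
            p2 = fisher_two_tailed(d, c, b, a).p_value
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_tailed(-1, 2, 3, 4)

    def test_odds_ratio_definition(self):
        res = fisher_two_tailed(10, 20, 5, 40)
        assert res.odds_ratio == pytest.approx((10 * 40) / (20 * 5))


class TestChisqYates:
    def test_matches_hand_formula(self):
        O = np.array([[30, 70], [10, 90]], dtype=float)
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        stat = (((np.abs(O - E) - 0.5) ** 2) / E).sum()
        res = chisq_yates(30, 70, 10, 90)
        assert res.p_value == pytest.approx(sps.chi2.sf(stat, 1))

    def test_yates_is_conservative(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(1, 60, 4))
            p_yates = chisq_yates(a, b, c, d).p_value
            p_raw = sps.chi2_contingency([[a, b], [c, d]], correction=False).pvalue
            assert p_yates >= p_raw - 1e-12


class TestCategoryEnrichment:
    def test_identical_labels_and_flags_maximally_associated(self):
        flags = {f"g{i}": i < 40 for i in range(120)}
        res = category_enrichment(flags, dict(flags))
        assert res.p_value < 1e-12

    def test_missing_labels_dropped_with_warning(self, caplog):
        flags = {"a": True, "b": False, "c": True, "d": False}
        labels = {"a": True, "b": False, "c": False}
        with caplog.at_level("WARNING"):
            res = category_enrichment(flags, labels)
        assert sum(res.table) == 3
        assert any("lack a label" in m for m in caplog.messages)

    def test_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(200)]
        flags = {g: bool(rng.integers(2)) for g in genes}
        labels = {g: bool(rng.integers(2)) for g in genes}
        p1 = category_enrichment(flags, labels).p_value
        shuffled = dict(sorted(flags.items(), key=lambda kv: hash(kv[0])))
        p2 = category_enrichment(shuffled, labels).p_value
        assert p1 == p2


class TestCodonUsageContingency:
    def make_orfeome(self, rng, n=40, length=200, boost_codon=None, boost_genes=(), rate=5):
        from rarecodon._codes import CODONS
        from rarecodon._codes import code_tables

        forward, _ = code_tables("standard")
        sense = [c for c in CODONS if c in forward]
        orfeome = []
        for g in range(n):
            codons = list(rng.choice(sense, length))
            if boost_codon and g in boost_genes:
                k = min(rate * 50 // 100, 50)
                pos = rng.choice(50, size=k, replace=False)
                for p in pos:
                    codons[p] = boost_codon
            orfeome.append(ORFRecord(f"g{g}", "".join(codons)))
        return orfeome

    def test_identical_groups_give_p_one(self, rng):
        orfeome = self.make_orfeome(rng)
        # both groups are random draws from the same process; a codon absent
        # everywhere gives a degenerate table with p = 1
        flags = {f"g{g}": g % 2 == 0 for g in range(40)}
        df = codon_usage_contingency(orfeome, flags)
        assert ((df["p_value"] > 1e-4) | df["unreliable"]).mean() > 0.95

    def test_planted_codon_detected_enriched(self, rng):
        boost = set(range(20))
        orfeome = self.make_orfeome(
            rng, n=60, length=300, boost_codon="CTA", boost_genes=boost, rate=30
        )
        flags = {f"g{g}": g in boost for g in range(60)}
        df = codon_usage_contingency(orfeome, flags).set_index("codon")
        row = df.loc["CTA"]
        assert row["p_value"] < 1e-3
        assert row["direction"] == "enriched"

    def test_too_few_genes_errors(self, rng):
        orfeome = self.make_orfeome(rng, n=3)
        with pytest.raises(ValueError):
            codon_usage_contingency(orfeome, {"g0": True, "g1": False, "g2": False})


class TestStratifyExpression:
    def test_threshold_examples(self):
        expr = {
            "hi": [2.5, 2.1],
            "mid": [1.5, 1.5],
            "lo": [1.0, 1.1],
            "edge_hi": [2.0, 2.0],   # mean exactly 2.0: excluded (strict >)
            "edge_lo": [1.15, 1.15],  # mean exactly 1.15: excluded (strict <)
        }
        high, low = stratify_expression(expr)
        assert high == {"hi"}
        assert low == {"lo"}

    def test_constructed_means_partition_exactly(self, rng):
        means = rng.uniform(0.5, 3.0, 200)
        expr = {f"g{i}": [m * f for f in (0.9, 1.0, 1.1)] for i, m in enumerate(means)}
        high, low = stratify_expression(expr)
        for i, m in enumerate(means):
            mean = m * (0.9 + 1.0 + 1.1) / 3
            assert (f"g{i}" in high) == (mean > 2.0)
            assert (f"g{i}" in low) == (mean < 1.15)

    def test_empty_ratio_list_errors(self):
        with pytest.raises(ValueError):
            stratify_expression({"g": []})
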