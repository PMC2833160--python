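"""Contingency statistics for gene classes and per-codon usage.

Gene-class enrichment (signal sequence, predicted secretion, functional
category, expression stratum) is tested with Fisher's exact two-tailed test
on the 2x2 table of label x cluster-in-range. Per-codon regional usage is
tested with a chi-square with Yates continuity correction on the 2x2 table
of (terminal count, interior count) x (genes with terminal clusters, genes
without). Expression strata are defined from averaged Cy5/Cy3 ratios.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._codes import CODON_INDEX, code_tables
from .orfeome import ORFRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "fisher_two_tailed",
    "category_enrichment",
    "codon_usage_contingency",
    "stratify_expression",
    "chisq_yates",
]


@dataclass
class ContingencyResult:
    table: tuple[int, int, int, int]  # (a, b, c, d) row-major
    odds_ratio: float
    p_value: float
    test: str
    description: str = ""

    def to_row(self) -> dict:
        a, b, c, d = self.table
        return {
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "test": self.test,
            "description": self.description,
        }


def fisher_two_tailed(a: int, b: int, c: int, d: int, description: str = "") -> ContingencyResult:
    """Fisher's exact two-tailed test on the 2x2 table [[a, b], [c, d]].

    Two-tailed p is the sum of hypergeometric probabilities of all tables
    (with the observed margins) at most as probable as the observed one —
    the dominant convention, as implemented by scipy. A table with an
    all-zero margin is degenerate and returns p = 1 (flagged in the log).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    tab = np.array([[a, b], [c, d]], dtype=np.int64)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table with an all-zero margin: %s", tab.tolist())
        orr = np.nan if b * c == 0 else (a * d) / (b * c)
        return ContingencyResult((a, b, c, d), orr, 1.0, "fisher_two_tailed", description)
    res = sps.fisher_exact(tab, alternative="two-sided")
    orr = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return ContingencyResult((a, b, c, d), float(orr), float(res.pvalue), "fisher_two_tailed", description)


def chisq_yates(a: int, b: int, c: int, d: int, description: str = "") -> ContingencyResult:
    """Chi-square with Yates continuity correction on [[a, b], [c, d]]."""
    tab = np.array([[a, b], [c, d]], dtype=np.int64)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 table with an all-zero margin: %s", tab.tolist())
        return ContingencyResult((a, b, c, d), np.nan, 1.0, "chisq_yates", description)
    res = sps.chi2_contingency(tab, correction=True)
    orr = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return ContingencyResult((a, b, c, d), float(orr), float(res.pvalue), "chisq_yates", description)


def category_enrichment(
    gene_flags: Mapping[str, bool],
    labels: Mapping[str, bool],
    description: str = "",
) -> ContingencyResult:
    """Fisher's exact test of a binary gene label against cluster-in-range
    flags. Genes missing a label are dropped with a warning."""
    genes = list(gene_flags)
    missing = [g for g in genes if g not in labels]
    if missing:
        logger.warning("%d genes lack a label and were dropped", len(missing))
    kept = [g for g in genes if g in labels]
    a = sum(1 for g in kept if labels[g] and gene_flags[g])
    b = sum(1 for g in kept if labels[g] and not gene_flags[g])
    c = sum(1 for g in kept if not labels[g] and gene_flags[g])
    d = sum(1 for g in kept if not labels[g] and not gene_flags[g])
    return fisher_two_tailed(a, b, c, d, description)


def _regional_codon_counts(
    orfeome: list[ORFRecord], genes: set[str], region_len: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(first, last, interior) 64-long codon count vectors over a gene set."""
    first = np.zeros(64, dtype=np.int64)
    last = np.zeros(64, dtype=np.int64)
    interior = np.zeros(64, dtype=np.int64)
    for orf in orfeome:
        if orf.gene_id not in genes:
            continue
        idx = orf.codon_indices
        idx = idx[idx >= 0]
        first += np.bincount(idx[:region_len], minlength=64)
        last += np.bincount(idx[-region_len:], minlength=64)
        mid = idx[region_len:-region_len]
        if len(mid):
            interior += np.bincount(mid, minlength=64)
    return first, last, interior


def codon_usage_contingency(
    orfeome: list[ORFRecord],
    group_flags: Mapping[str, bool],
    region: str = "first50",
    region_len: int = 50,
    genetic_code: str = "standard",
) -> pd.DataFrame:
    """Per-codon 2x2 chi-square (Yates) of terminal versus interior usage
    between two gene groups.

    For each sense codon, the table is
    [[count in region, count in interior] for group True,
     [count in region, count in interior] for group False].
    ``region`` is "first50" or "last50" ("interior" tests interior versus
    pooled terminal usage). Reports raw p, Bonferroni-adjusted p across the
    61 sense codons, the enrichment direction in the flagged group, and an
    unreliable flag when any expected cell is < 1.
    """
    forward, _ = code_tables(genetic_code)
    g_true = {g for g, f in group_flags.items() if f}
    g_false = {g for g, f in group_flags.items() if not f}
    if len(g_true) < 2 or len(g_false) < 2:
        raise ValueError("need >= 2 genes in each group")
    f_t, l_t, i_t = _regional_codon_counts(orfeome, g_true, region_len)
    f_f, l_f, i_f = _regional_codon_counts(orfeome, g_false, region_len)
    if region == "first50":
        r_t, r_f = f_t, f_f
    elif region == "last50":
        r_t, r_f = l_t, l_f
    elif region == "interior":
        r_t, r_f = i_t, i_f
        i_t, i_f = f_t + l_t, f_f + l_f
    else:
        raise ValueError(f"unknown region: {region!r}")
    rows = []
    for codon, aa in sorted(forward.items()):
        k = CODON_INDEX[codon]
        a, b = int(r_t[k]), int(i_t[k])
        c, d = int(r_f[k]), int(i_f[k])
        tab = np.array([[a, b], [c, d]], dtype=float)
        degenerate = (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any()
        if degenerate:
            p, unreliable, direction = 1.0, True, "none"
        else:
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            unreliable = bool((expected < 1).any())
            res = sps.chi2_contingency(tab, correction=True)
            p = float(res.pvalue)
            direction = "enriched" if a * (c + d) > c * (a + b) else "depleted"
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa,
                "region_count_group": a,
                "interior_count_group": b,
                "region_count_rest": c,
                "interior_count_rest": d,
                "p_value": p,
                "direction": direction,
                "unreliable": unreliable,
            }
        )
    df = pd.DataFrame(rows)
    m = len(df)
    df["p_bonferroni"] = np.minimum(df["p_value"] * m, 1.0)
    return df


def stratify_expression(
    expr: Mapping[str, list[float]], hi: float = 2.0, lo: float = 1.15
) -> tuple[set[str], set[str]]:
    """Split genes into highly / least expressed sets by mean Cy5/Cy3 ratio.

    Per-gene ratios (one per experiment) are averaged; genes with mean > hi
    form the high set, mean < lo the low set; the rest belong to neither.
    Non-positive ratios are retained with a warning.
    """
    high: set[str] = set()
    low: set[str] = set()
    for gene, ratios in expr.items():
        if len(ratios) == 0:
            raise ValueError(f"{gene}: no expression ratios")
        arr = np.asarray(ratios, dtype=float)
        if (arr <= 0).any():
            logger.warning("%s: non-positive Cy5/Cy3 ratio retained", gene)
        mean = float(arr.mean())
        if mean > hi:
            high.add(gene)
        elif mean < lo:
            low.add(gene)
    return high, low
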