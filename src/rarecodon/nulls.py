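"""Synonymous randomization null models.

Two nulls, both of which preserve the encoded protein (and gene length)
exactly:

* weighted random reverse translation — every codon is independently
  resampled from its synonymous family with the usage-table probabilities
  X_ij; this is the primary null for positional cluster statistics.
* dinucleotide-preserving shuffle — a Markov chain of synonymous moves
  (single-codon substitutions and same-amino-acid codon swaps) in which a
  proposal is accepted only if it leaves all 16 dinucleotide counts of the
  coding sequence — including the counts spanning codon boundaries —
  unchanged. The stationary sequences are synonymous re-encodings with the
  input's exact dinucleotide composition (and therefore exact GC content).

Randomness is driven by numpy SeedSequences keyed on (seed, replicate, gene
index), so per-gene results do not depend on iteration order.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from ._codes import CODONS, code_tables, synonymous_families
from .orfeome import CodonUsageTable, ORFRecord

logger = logging.getLogger(__name__)

__all__ = [
    "reverse_translate_random",
    "dinucleotide_preserving_shuffle",
    "randomize_orfeome",
    "dinucleotide_counts",
]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def reverse_translate_random(
    orf: ORFRecord, table: CodonUsageTable, rng_seed
) -> ORFRecord:
    """Resample every sense codon from its synonymous family with usage-table
    weights. Stop codons and non-ATGC codons are left untouched."""
    from ._encoded import resample_weighted

    rng = _as_rng(rng_seed)
    new_idx = resample_weighted(orf.codon_indices, table, rng)
    seq = _rebuild_seq(orf, new_idx)
    return ORFRecord(orf.gene_id, seq, labels=orf.labels,
                     has_internal_stop=orf.has_internal_stop,
                     stop_stripped=orf.stop_stripped)


def _rebuild_seq(orf: ORFRecord, new_idx: np.ndarray) -> str:
    parts = []
    for i, k in enumerate(new_idx):
        if k < 0:
            parts.append(orf.nt_seq[3 * i : 3 * i + 3])
        else:
            parts.append(CODONS[k])
    return "".join(parts)


def dinucleotide_counts(nt_seq: str) -> Counter:
    """All 16 overlapping dinucleotide counts of a sequence."""
    return Counter(nt_seq[i : i + 2] for i in range(len(nt_seq) - 1))


def dinucleotide_preserving_shuffle(
    orf: ORFRecord, rng_seed, n_swaps: int | None = None,
    genetic_code: str = "standard",
) -> ORFRecord:
    """Synonymous randomization that conserves all 16 dinucleotide counts
    exactly.

    Runs ``n_swaps`` proposals (default 10x gene length): with equal
    probability either a synonymous substitution at one position or a codon
    swap between two positions encoding the same amino acid; a proposal is
    accepted only when the local dinucleotide multiset (the up-to-four
    dinucleotides touching each changed codon) is unchanged, which implies
    the global counts are conserved. A sequence admitting no accepted move is
    returned unchanged (flagged via a log message).
    """
    rng = _as_rng(rng_seed)
    forward, stops = code_tables(genetic_code)
    fams = synonymous_families(genetic_code)
    codons = orf.codons
    n = len(codons)
    if n_swaps is None:
        n_swaps = 10 * n
    # positions eligible for synonymous moves: sense codons with >1 synonym
    aa_at: list[str | None] = []
    for c in codons:
        aa = forward.get(c)
        aa_at.append(aa if aa is not None and len(fams[aa]) > 1 else None)
    eligible = [i for i, aa in enumerate(aa_at) if aa is not None]
    if not eligible:
        return ORFRecord(orf.gene_id, orf.nt_seq, labels=orf.labels,
                         has_internal_stop=orf.has_internal_stop,
                         stop_stripped=orf.stop_stripped)
    by_aa: dict[str, list[int]] = {}
    for i in eligible:
        by_aa.setdefault(aa_at[i], []).append(i)

    def local_dinucs(seq_codons, i, new_c=None):
        c = new_c if new_c is not None else seq_codons[i]
        out = [c[0:2], c[1:3]]
        if i > 0:
            out.append(seq_codons[i - 1][2] + c[0])
        if i < n - 1:
            out.append(c[2] + seq_codons[i + 1][0])
        return out

    accepted = 0
    for _ in range(n_swaps):
        if rng.random() < 0.5:
            i = eligible[rng.integers(len(eligible))]
            aa = aa_at[i]
            syns = fams[aa]
            new_c = syns[rng.integers(len(syns))]
            if new_c == codons[i]:
                continue
            before = Counter(local_dinucs(codons, i))
            after = Counter(local_dinucs(codons, i, new_c))
            if before == after:
                codons[i] = new_c
                accepted += 1
        else:
            aa = aa_at[eligible[rng.integers(len(eligible))]]
            group = by_aa[aa]
            if len(group) < 2:
                continue
            i, j = group[rng.integers(len(group))], group[rng.integers(len(group))]
            if i == j or codons[i] == codons[j]:
                continue
            if i > j:
                i, j = j, i
            affected = range(max(i - 1, 0), min(j + 2, n)) if j - i <= 2 else None
            if affected is None:
                before = Counter(local_dinucs(codons, i)) + Counter(local_dinucs(codons, j))
                ci, cj = codons[i], codons[j]
                codons[i], codons[j] = cj, ci
                after = Counter(local_dinucs(codons, i)) + Counter(local_dinucs(codons, j))
                if before == after:
                    accepted += 1
                else:
                    codons[i], codons[j] = ci, cj
            else:
                span = list(affected)
                before = Counter(
                    codons[k][a] + (codons[k][a + 1] if a < 2 else codons[k + 1][0])
                    for k in span
                    for a in range(3)
                    if a < 2 or k + 1 < n
                )
                ci, cj = codons[i], codons[j]
                codons[i], codons[j] = cj, ci
                after = Counter(
                    codons[k][a] + (codons[k][a + 1] if a < 2 else codons[k + 1][0])
                    for k in span
                    for a in range(3)
                    if a < 2 or k + 1 < n
                )
                if before == after:
                    accepted += 1
                else:
                    codons[i], codons[j] = ci, cj
    if accepted == 0:
        logger.info("%s: no dinucleotide-conserving move accepted; returned unchanged",
                    orf.gene_id)
    return ORFRecord(orf.gene_id, "".join(codons), labels=orf.labels,
                     has_internal_stop=orf.has_internal_stop,
                     stop_stripped=orf.stop_stripped)


def gene_rng(seed: int, rep: int, gene_index: int) -> np.random.Generator:
    """Deterministic per-(replicate, gene) stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(rep, gene_index))
    )


def randomize_orfeome(
    orfeome: list[ORFRecord],
    method: str = "weighted",
    n_reps: int = 1,
    seed: int = 0,
    table: CodonUsageTable | None = None,
    n_swaps: int | None = None,
) -> list[list[ORFRecord]]:
    """Generate ``n_reps`` independent randomized replicates of an ORFeome.

    ``method`` is "weighted" (random reverse translation; requires ``table``)
    or "dinucleotide". Reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method == "weighted":
        if table is None:
            raise ValueError("weighted randomization requires a usage table")
        return [
            [
                reverse_translate_random(orf, table, gene_rng(seed, rep, g))
                for g, orf in enumerate(orfeome)
            ]
            for rep in range(n_reps)
        ]
    if method == "dinucleotide":
        return [
            [
                dinucleotide_preserving_shuffle(orf, gene_rng(seed, rep, g), n_swaps)
                for g, orf in enumerate(orfeome)
            ]
            for rep in range(n_reps)
        ]
    raise ValueError(f"unknown randomization method: {method!r}")
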