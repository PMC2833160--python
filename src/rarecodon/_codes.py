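"""Genetic-code lookups shared across modules.

Codons are indexed 0..63 in lexicographic A/C/G/T order; index -1 marks a
codon containing a non-ATGC base. The standard genetic code is taken from
Biopython's codon tables (the canonical 20 amino acids are identical under
the bacterial table, so "standard" is the default for prokaryotic ORFeomes).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}
CODONS = [a + b + c for a in NT for b in NT for c in NT]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: map of friendly genetic-code ids to NCBI table ids
GENETIC_CODE_IDS = {"standard": 1, "bacterial": 11}


@lru_cache(maxsize=None)
def code_tables(genetic_code: str = "standard"):
    """Return (forward: dict codon->aa for sense codons, stop_codons: frozenset)."""
    try:
        ncbi_id = GENETIC_CODE_IDS[genetic_code]
    except KeyError:
        raise ValueError(f"unknown genetic code id: {genetic_code!r}") from None
    table = CodonTable.unambiguous_dna_by_id[ncbi_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def synonymous_families(genetic_code: str = "standard"):
    """Map amino acid (one-letter) -> tuple of synonymous codons, sorted."""
    forward, _ = code_tables(genetic_code)
    fam: dict[str, list[str]] = {}
    for codon, aa in forward.items():
        fam.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fam.items()}


def encode_codons(nt_seq: str) -> np.ndarray:
    """Encode a coding sequence into codon indices; -1 for non-ATGC codons."""
    n = len(nt_seq) // 3
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        codon = nt_seq[3 * i : 3 * i + 3]
        idx[i] = CODON_INDEX.get(codon, -1)
    return idx


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)
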