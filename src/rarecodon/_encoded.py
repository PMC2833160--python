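"""Flat, vectorized representation of an ORFeome for the heavy loops.

Genes are concatenated into one codon-index array with offsets; window sums,
cluster flags and weighted-null resampling are then single numpy operations
over the whole ORFeome, which is what makes 50-replicate positional null
profiles affordable. Windows never span gene boundaries: gene g contributes
windows starting at offsets[g]..offsets[g]+n_windows(len_g)-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codes import CODON_INDEX
from .orfeome import CodonUsageTable, ORFRecord, n_windows
from ._codes import synonymous_families

__all__ = ["EncodedOrfeome", "window_values_flat", "resample_weighted", "family_matrices"]


@dataclass
class EncodedOrfeome:
    idx: np.ndarray          # concatenated codon indices, -1 = non-ATGC
    offsets: np.ndarray      # gene g occupies idx[offsets[g]:offsets[g+1]]
    gene_ids: list[str]
    window: int

    @classmethod
    def from_orfeome(cls, orfeome: list[ORFRecord], window: int = 18) -> "EncodedOrfeome":
        parts = [orf.codon_indices for orf in orfeome]
        lengths = np.array([len(p) for p in parts], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        idx = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)
        return cls(idx, offsets, [o.gene_id for o in orfeome], window)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def gene_lengths(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def window_counts(self) -> np.ndarray:
        return np.maximum(self.gene_lengths - self.window, 0)

    @property
    def window_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.window_counts)])

    @property
    def window_starts(self) -> np.ndarray:
        """Global codon index of each window start, all genes concatenated."""
        nw = self.window_counts
        reps = np.repeat(self.offsets[:-1], nw)
        local = np.concatenate([np.arange(k) for k in nw]) if nw.sum() else np.zeros(0, dtype=np.int64)
        return reps + local


def window_values_flat(
    enc: EncodedOrfeome, idx: np.ndarray, table: CodonUsageTable
) -> np.ndarray:
    """%MinMax values for every window of every gene, concatenated.

    ``idx`` is a codon-index array matching ``enc`` (the original or a
    resampled one). Masked windows are NaN.
    """
    W = enc.window
    safe = np.clip(idx, 0, 63)
    sense = (idx >= 0) & table._sense[safe]
    starts = enc.window_starts
    if len(starts) == 0:
        return np.zeros(0)

    def wsum(v):
        cs = np.concatenate([[0.0], np.cumsum(v)])
        return cs[starts + W] - cs[starts]

    x = np.where(sense, table._x[safe], 0.0)
    A = wsum(x)
    V = wsum(np.where(sense, table._xavg[safe], 0.0))
    Mx = wsum(np.where(sense, table._xmax[safe], 0.0))
    Mn = wsum(np.where(sense, table._xmin[safe], 0.0))
    csb = np.concatenate([[0], np.cumsum(~sense)])
    ok = (csb[starts + W] - csb[starts]) == 0
    up = A >= V
    num = np.where(up, A - V, V - A)
    den = np.where(up, Mx - V, V - Mn)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, 100.0 * num / den, 0.0)
    vals = np.where(up, vals, -vals)
    return np.where(ok, vals, np.nan)


def family_matrices(table: CodonUsageTable):
    """(members, cum) 64 x max_family matrices for vectorized resampling.

    Row k lists the synonymous-family member codon indices of sense codon k
    (padded by repeating the last member) and the cumulative within-family
    probabilities (padded with +inf sentinels at 2.0).
    """
    cache = table.__dict__.get("_family_matrices")
    if cache is not None:
        return cache
    fams = synonymous_families(table.genetic_code_id)
    width = max(len(cs) for cs in fams.values())
    members = np.zeros((64, width), dtype=np.int64)
    cum = np.full((64, width), 2.0)
    for aa, cs in fams.items():
        idxs = np.array([CODON_INDEX[c] for c in cs], dtype=np.int64)
        probs = np.array([table.freq[c] for c in cs], dtype=float)
        total = probs.sum()
        probs = probs / total if total > 0 else np.full(len(cs), 1.0 / len(cs))
        c = np.cumsum(probs)
        c[-1] = 1.0
        for k in idxs:
            members[k, : len(cs)] = idxs
            members[k, len(cs):] = idxs[-1]
            cum[k, : len(cs)] = c
    table.__dict__["_family_matrices"] = (members, cum)
    return members, cum


def resample_weighted(
    idx: np.ndarray, table: CodonUsageTable, rng: np.random.Generator
) -> np.ndarray:
    """Weighted random reverse translation on a codon-index array; stop and
    non-ATGC codons pass through unchanged."""
    members, cum = family_matrices(table)
    safe = np.clip(idx, 0, 63)
    sense = (idx >= 0) & table._sense[safe]
    out = idx.copy()
    pos = np.nonzero(sense)[0]
    if len(pos) == 0:
        return out
    rows = idx[pos]
    u = rng.random(len(pos))
    sel = (u[:, None] >= cum[rows]).sum(axis=1)
    out[pos] = members[rows, sel]
    return out
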