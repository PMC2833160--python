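"""The %MinMax sliding-window codon usage statistic.

For a window of W codons, let A be the sum of the actual within-family usage
frequencies X_ij over the window, and V, Mx, Mn the corresponding sums of the
per-amino-acid average, maximum and minimum family frequencies. The window
value is

    +100 * (A - V) / (Mx - V)   if A >= V   (%Max, common-codon enriched)
    -100 * (V - A) / (V - Mn)   otherwise   (%Min, rare-codon enriched)

so a window built entirely from each amino acid's most common codon scores
+100 and one built from the least common codons scores -100; the organism's
average usage is the 0 baseline. A degenerate denominator (e.g. a window of
Met/Trp only, or a uniform table) yields 0. Windows containing a non-ATGC
base or a stop codon are masked (NaN).

A gene of n codons yields n - W values, one per window start 1..n-W; windows
that would run past this range are not scored (see orfeome.n_windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orfeome import CodonUsageTable, ORFRecord, n_windows

__all__ = ["MinMaxProfile", "minmax_window", "score_orfeome", "score_gene", "profiles_to_frame"]

CONVENTION = "windows 1..n-W of W codons; signed %Min(-)/%Max(+); masked=NaN"


@dataclass
class MinMaxProfile:
    """Per-gene vector of %MinMax window values.

    ``values[i]`` is the score of the window starting at codon i+1 (1-based);
    masked windows are NaN. All non-masked values lie in [-100, +100].
    """

    gene_id: str
    window_size: int
    values: np.ndarray
    convention_id: str = CONVENTION

    @property
    def masked(self) -> np.ndarray:
        return np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _window_stats(idx: np.ndarray, table: CodonUsageTable, window: int):
    """Vectorized window sums (A, V, Mx, Mn, ok) for codon-index array ``idx``."""
    n = len(idx)
    nw = n_windows(n, window)
    if nw <= 0:
        z = np.zeros(0)
        return z, z, z, z, np.zeros(0, dtype=bool)
    safe = np.clip(idx, 0, 63)
    sense = (idx >= 0) & table._sense[safe]
    x = np.where(sense, table._x[safe], 0.0)
    xavg = np.where(sense, table._xavg[safe], 0.0)
    xmax = np.where(sense, table._xmax[safe], 0.0)
    xmin = np.where(sense, table._xmin[safe], 0.0)

    def wsum(v):
        cs = np.concatenate([[0.0], np.cumsum(v)])
        return cs[window : window + nw] - cs[:nw]

    bad = np.concatenate([[0], np.cumsum(~sense)])
    ok = (bad[window : window + nw] - bad[:nw]) == 0
    return wsum(x), wsum(xavg), wsum(xmax), wsum(xmin), ok


def _values_from_sums(A, V, Mx, Mn, ok) -> np.ndarray:
    up = A >= V
    num = np.where(up, A - V, V - A)
    den = np.where(up, Mx - V, V - Mn)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, 100.0 * num / den, 0.0)
    vals = np.where(up, vals, -vals)
    vals = np.where(ok, vals, np.nan)
    return vals


def minmax_window(codons: list[str], table: CodonUsageTable) -> float:
    """Score a single window of codons. Raises KeyError for codons absent
    from the table (stop codons, non-ATGC codons)."""
    A = V = Mx = Mn = 0.0
    for c in codons:
        if c not in table.aa_of:
            raise KeyError(f"codon {c!r} is not a sense codon in the usage table")
        aa = table.aa_of[c]
        A += table.freq[c]
        V += table.x_avg[aa]
        Mx += table.x_max[aa]
        Mn += table.x_min[aa]
    if A >= V:
        return 100.0 * (A - V) / (Mx - V) if Mx > V else 0.0
    return -100.0 * (V - A) / (V - Mn) if V > Mn else 0.0


def score_gene(
    orf: ORFRecord, table: CodonUsageTable, window: int = 18
) -> MinMaxProfile:
    A, V, Mx, Mn, ok = _window_stats(orf.codon_indices, table, window)
    return MinMaxProfile(orf.gene_id, window, _values_from_sums(A, V, Mx, Mn, ok))


def score_orfeome(
    orfeome: list[ORFRecord], table: CodonUsageTable, window: int = 18
) -> list[MinMaxProfile]:
    """Score every gene; genes shorter than window+1 codons yield an empty
    (flagged) profile."""
    return [score_gene(orf, table, window) for orf in orfeome]


def profiles_to_frame(profiles: list[MinMaxProfile]) -> pd.DataFrame:
    """Long-form table: gene_id, window_start (1-based codon coordinate),
    value, masked."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": p.gene_id,
                    "window_start": np.arange(1, len(p.values) + 1),
                    "value": p.values,
                    "masked": p.masked,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene_id", "window_start", "value", "masked"])
    return pd.concat(frames, ignore_index=True)
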