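"""ORFeome input, validation, codon usage tables, and the gene-length filter.

An ORFeome is a multi-FASTA of coding nucleotide sequences, each running from
the start codon through (optionally) the stop codon. Reading normalizes case,
maps U to T, strips a terminal stop codon, and excludes records whose length
is not a multiple of three. Codon usage is tallied over sense codons only:
%MinMax is defined over synonymous families of amino acids, so stop codons
never enter the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codes import CODONS, CODON_INDEX, code_tables, encode_codons, synonymous_families

logger = logging.getLogger(__name__)

__all__ = [
    "ORFRecord",
    "CodonUsageTable",
    "read_orfeome",
    "write_orfeome",
    "compute_usage_table",
    "filter_by_length",
    "n_windows",
    "gene_metadata",
    "write_usage_table",
]


def n_windows(length_codons: int, window: int = 18) -> int:
    """Number of scored windows for a gene of ``length_codons`` codons.

    A gene of n codons is scored at windows 1..n-W (window i covering codons
    i..i+W-1). This count convention makes the 250-window length filter
    equivalent to >= 268 codons; the final full window (starting at n-W+1)
    is intentionally not scored. See the package methods note for the
    rationale behind this convention.
    """
    return max(length_codons - window, 0)


@dataclass
class ORFRecord:
    """A single open reading frame.

    ``nt_seq`` is the uppercase A/C/G/T (plus ambiguity letters) coding
    sequence without the terminal stop codon. ``labels`` carries optional
    annotations (signal, secreted, category, expression_ratio).
    """

    gene_id: str
    nt_seq: str
    labels: dict | None = None
    has_internal_stop: bool = False
    stop_stripped: bool = False
    _codon_idx: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.nt_seq) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.nt_seq)} is not a multiple of 3"
            )

    @property
    def codons(self) -> list[str]:
        s = self.nt_seq
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    @property
    def length_codons(self) -> int:
        return len(self.nt_seq) // 3

    @property
    def codon_indices(self) -> np.ndarray:
        """Codon indices (0..63; -1 for codons with a non-ATGC base), cached."""
        if self._codon_idx is None:
            self._codon_idx = encode_codons(self.nt_seq)
        return self._codon_idx

    def protein(self, genetic_code: str = "standard") -> str:
        forward, stops = code_tables(genetic_code)
        out = []
        for c in self.codons:
            if c in stops:
                out.append("*")
            else:
                out.append(forward.get(c, "X"))
        return "".join(out)


@dataclass
class CodonUsageTable:
    """Within-synonymous-family codon usage frequencies.

    For amino acid i with n synonymous codons, ``freq[codon]`` is X_ij, the
    fraction of that amino acid's occurrences encoded by codon j, so the
    family frequencies sum to 1 and the family average X_avg,i is 1/n.
    Per-family minima and maxima (X_min,i, X_max,i) are derived. Single-codon
    families (Met, Trp under the standard code) have X_min = X_avg = X_max = 1.
    """

    freq: dict[str, float]
    counts: dict[str, int] | None = None
    genetic_code_id: str = "standard"

    def __post_init__(self) -> None:
        forward, _ = code_tables(self.genetic_code_id)
        fams = synonymous_families(self.genetic_code_id)
        self.aa_of = forward
        self.n_syn = {aa: len(cs) for aa, cs in fams.items()}
        self.x_min = {aa: min(self.freq[c] for c in cs) for aa, cs in fams.items()}
        self.x_max = {aa: max(self.freq[c] for c in cs) for aa, cs in fams.items()}
        self.x_avg = {aa: 1.0 / len(cs) for aa in fams for cs in [fams[aa]]}
        # dense per-codon-index arrays for the vectorized scorer
        x = np.zeros(64)
        xavg = np.zeros(64)
        xmax = np.zeros(64)
        xmin = np.zeros(64)
        sense = np.zeros(64, dtype=bool)
        for codon, aa in forward.items():
            k = CODON_INDEX[codon]
            x[k] = self.freq[codon]
            xavg[k] = self.x_avg[aa]
            xmax[k] = self.x_max[aa]
            xmin[k] = self.x_min[aa]
            sense[k] = True
        self._x, self._xavg, self._xmax, self._xmin, self._sense = x, xavg, xmax, xmin, sense

    def validate(self, atol: float = 1e-9) -> None:
        """Check within-family normalization and min <= avg <= max."""
        fams = synonymous_families(self.genetic_code_id)
        for aa, cs in fams.items():
            total = sum(self.freq[c] for c in cs)
            if abs(total - 1.0) > atol:
                raise ValueError(f"family {aa}: frequencies sum to {total}, expected 1")
            if not (self.x_min[aa] <= self.x_avg[aa] + atol and self.x_avg[aa] <= self.x_max[aa] + atol):
                raise ValueError(f"family {aa}: min/avg/max out of order")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for codon, aa in sorted(self.aa_of.items()):
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "count": None if self.counts is None else self.counts.get(codon, 0),
                    "frequency": self.freq[codon],
                }
            )
        return pd.DataFrame(rows)


def read_orfeome(
    fasta_path: str | Path,
    genetic_code: str = "standard",
    strip_stop: bool = True,
    exclude_internal_stops: bool = False,
) -> list[ORFRecord]:
    """Read a multi-FASTA nucleotide ORFeome.

    Sequences are uppercased and U is mapped to T. Records whose length is
    not a multiple of three are excluded with a warning. A terminal stop
    codon is stripped when present. Records containing internal stop codons
    are retained but flagged (set ``exclude_internal_stops`` to drop them);
    non-ATGC bases are retained at the record level — windows overlapping
    them are masked downstream.
    """
    path = Path(fasta_path)
    records: list[ORFRecord] = []
    _, stops = code_tables(genetic_code)
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) == 0:
            logger.warning("%s: empty sequence, excluded", rec.id)
            n_skipped += 1
            continue
        if len(seq) % 3 != 0:
            logger.warning(
                "%s: length %d not a multiple of 3, excluded", rec.id, len(seq)
            )
            n_skipped += 1
            continue
        stop_stripped = False
        if strip_stop and seq[-3:] in stops:
            seq = seq[:-3]
            stop_stripped = True
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        internal = any(c in stops for c in codons)
        if internal:
            if exclude_internal_stops:
                logger.warning("%s: internal stop codon, excluded", rec.id)
                n_skipped += 1
                continue
            logger.warning("%s: internal stop codon, retained and flagged", rec.id)
        records.append(
            ORFRecord(rec.id, seq, has_internal_stop=internal, stop_stripped=stop_stripped)
        )
    if not records and n_skipped == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if not records:
        raise ValueError(f"{path}: no usable records ({n_skipped} excluded)")
    return records


def write_orfeome(orfeome: list[ORFRecord], fasta_path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(orf.nt_seq), id=orf.gene_id, description="") for orf in orfeome
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")


def compute_usage_table(
    orfeome: list[ORFRecord], genetic_code: str = "standard"
) -> CodonUsageTable:
    """Tally within-family codon usage frequencies over an ORFeome.

    Stop codons and codons containing non-ATGC bases are excluded. An amino
    acid with zero observations gets uniform within-family frequencies and a
    warning.
    """
    if not orfeome:
        raise ValueError("cannot compute a usage table from an empty ORFeome")
    forward, _ = code_tables(genetic_code)
    fams = synonymous_families(genetic_code)
    counts = np.zeros(64, dtype=np.int64)
    for orf in orfeome:
        idx = orf.codon_indices
        counts += np.bincount(idx[idx >= 0], minlength=64)
    count_of = {c: int(counts[k]) for k, c in enumerate(CODONS) if c in forward}
    freq: dict[str, float] = {}
    for aa, cs in fams.items():
        total = sum(count_of[c] for c in cs)
        if total == 0:
            logger.warning("amino acid %s: no observations; uniform frequencies used", aa)
            for c in cs:
                freq[c] = 1.0 / len(cs)
        else:
            for c in cs:
                freq[c] = count_of[c] / total
    return CodonUsageTable(freq=freq, counts=count_of, genetic_code_id=genetic_code)


def _unmasked_windows(orf: ORFRecord, window: int, genetic_code: str = "standard") -> int:
    """Count scored windows that contain only sense A/C/G/T codons."""
    nw = n_windows(orf.length_codons, window)
    if nw <= 0:
        return 0
    idx = orf.codon_indices[: orf.length_codons]
    _, stops = code_tables(genetic_code)
    bad = (idx < 0).astype(np.int64)
    if orf.has_internal_stop:
        codons = orf.codons
        bad |= np.fromiter((c in stops for c in codons), dtype=np.int64, count=len(codons))
    cs = np.concatenate([[0], np.cumsum(bad)])
    return int(np.sum((cs[window : window + nw] - cs[:nw]) == 0))


def filter_by_length(
    orfeome: list[ORFRecord],
    min_windows: int = 250,
    window: int = 18,
    count_masked: bool = False,
) -> list[ORFRecord]:
    """Retain genes with at least ``min_windows`` complete scored windows.

    With the default window of 18 codons, 250 windows corresponds to genes of
    at least 268 codons. Only unmasked windows (all-ATGC, no internal stop)
    count toward the threshold unless ``count_masked`` is set.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kept = []
    for orf in orfeome:
        nw = (
            n_windows(orf.length_codons, window)
            if count_masked
            else _unmasked_windows(orf, window)
        )
        if nw >= min_windows:
            kept.append(orf)
    logger.info(
        "length filter (>=%d windows of %d codons): retained %d/%d genes",
        min_windows,
        window,
        len(kept),
        len(orfeome),
    )
    return kept


def gene_metadata(
    orfeome: list[ORFRecord], min_windows: int = 250, window: int = 18
) -> pd.DataFrame:
    """Per-gene metadata table: id, length, window count, retained flag."""
    rows = []
    for orf in orfeome:
        nw = _unmasked_windows(orf, window)
        rows.append(
            {
                "gene_id": orf.gene_id,
                "length_codons": orf.length_codons,
                "n_windows": nw,
                "retained": nw >= min_windows,
                "has_internal_stop": orf.has_internal_stop,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["window_convention"] = (
        "windows 1..n-W; the final full window (start n-W+1) is not scored"
    )
    return df


def write_usage_table(table: CodonUsageTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
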