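"""Rare codon cluster calls and terminal-enrichment topology.

A window is part of a rare codon cluster when its %MinMax value is at or
below a negative threshold tau (-10 %Min by default, the point at which
rare-codon enrichment is statistically significant in E. coli). The module
calls per-gene clusters, calibrates tau per organism against randomized
nulls, counts genes with clusters in terminal ranges, and computes the
per-position fraction of genes carrying a cluster at each window position
from either terminus, with a z-score against weighted-reverse-translation
null replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encoded import EncodedOrfeome, resample_weighted, window_values_flat
from .minmax import MinMaxProfile
from .nulls import gene_rng
from .orfeome import CodonUsageTable, ORFRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterCallSet",
    "PositionalEnrichmentProfile",
    "ThresholdCalibration",
    "call_clusters",
    "call_orfeome_clusters",
    "calibrate_threshold",
    "positional_profile",
    "classify_terminal_genes",
    "null_cluster_sets",
    "clusters_to_frame",
    "DEFAULT_TERMINAL_RANGES",
]

DEFAULT_TAU = -10.0
#: (name, start, end) ranges in window coordinates from a terminus
DEFAULT_TERMINAL_RANGES = (
    ("terminal_1", 1, 1),
    ("first_25", 1, 25),
    ("first_50", 1, 50),
    ("windows_101_150", 101, 150),
    ("windows_151_200", 151, 200),
)


@dataclass
class ClusterCallSet:
    """Boolean per-window cluster flags and maximal flagged intervals."""

    gene_id: str
    tau: float
    flags: np.ndarray
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.flags)


def _intervals_from_flags(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 1-based (start, end) window coordinates."""
    if len(flags) == 0 or not flags.any():
        return []
    f = flags.astype(np.int8)
    d = np.diff(np.concatenate([[0], f, [0]]))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def call_clusters(profile: MinMaxProfile, tau: float = DEFAULT_TAU) -> ClusterCallSet:
    """Flag windows with value <= tau (masked windows never flagged)."""
    if tau >= 0:
        raise ValueError("tau must be negative (%Min threshold)")
    with np.errstate(invalid="ignore"):
        flags = np.where(np.isnan(profile.values), False, profile.values <= tau)
    return ClusterCallSet(profile.gene_id, tau, flags, _intervals_from_flags(flags))


def call_orfeome_clusters(
    profiles: list[MinMaxProfile], tau: float = DEFAULT_TAU
) -> list[ClusterCallSet]:
    return [call_clusters(p, tau) for p in profiles]


@dataclass
class ThresholdCalibration:
    tau: float
    significant: bool
    z_min: float
    table: pd.DataFrame  # per-candidate: tau, observed, null_mean, null_sd, z


def calibrate_threshold(
    orfeome: list[ORFRecord],
    table: CodonUsageTable,
    null_reps: int = 50,
    candidate_taus: tuple[float, ...] = tuple(np.arange(-10.0, -61.0, -5.0)),
    z_min: float = 3.0,
    seed: int = 0,
    window: int = 18,
    default_tau: float = DEFAULT_TAU,
) -> ThresholdCalibration:
    """Pick the least-stringent tau at which the real ORFeome's genome-wide
    count of windows <= tau exceeds the weighted-null expectation by at
    least ``z_min`` null standard deviations.

    Candidates default to -10 (the baseline threshold) escalating in -5
    steps to -60: the threshold is only ever made more stringent than the
    -10 default, never laxer. Organisms with no significant candidate keep
    ``default_tau`` and are flagged not-significant, mirroring the fallback
    used for genomes where no %Min level reaches significance.
    """
    if not candidate_taus:
        raise ValueError("candidate_taus must be non-empty")
    if null_reps < 2:
        raise ValueError("need >= 2 null replicates to estimate a null SD")
    taus = np.array(sorted(candidate_taus, reverse=True), dtype=float)  # -5 first
    enc = EncodedOrfeome.from_orfeome(orfeome, window)
    real_vals = window_values_flat(enc, enc.idx, table)
    obs = np.array([np.nansum(real_vals <= t) for t in taus], dtype=float)
    null_counts = np.empty((null_reps, len(taus)))
    for rep in range(null_reps):
        idx = resample_weighted(enc.idx, table, gene_rng(seed, rep, 0))
        vals = window_values_flat(enc, idx, table)
        null_counts[rep] = [np.nansum(vals <= t) for t in taus]
    mean = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.inf * np.sign(obs - mean))
    df = pd.DataFrame(
        {"tau": taus, "observed": obs, "null_mean": mean, "null_sd": sd, "z": z}
    )
    hits = np.nonzero((z >= z_min) & (obs > mean))[0]
    if len(hits) == 0:
        logger.warning(
            "no candidate threshold significant at z >= %.1f; defaulting to %g",
            z_min,
            default_tau,
        )
        return ThresholdCalibration(default_tau, False, z_min, df)
    return ThresholdCalibration(float(taus[hits[0]]), True, z_min, df)


@dataclass
class PositionalEnrichmentProfile:
    """Percent of genes with a cluster at each window position from a
    terminus, with the same quantity under null replicates."""

    orientation: str  # "5prime" | "3prime"
    position: np.ndarray  # 1..max_pos from the terminus
    pct_genes: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray  # NaN where null_sd == 0
    n_genes: int
    n_null_reps: int
    nonterminal_mean: float | None = None
    nonterminal_sd: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orientation": self.orientation,
                "position": self.position,
                "pct_genes": self.pct_genes,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
            }
        )


def _terminal_flag_matrix(
    cluster_sets: list[ClusterCallSet], orientation: str, max_pos: int
) -> np.ndarray:
    """Gene x position boolean matrix of flags counted from the terminus."""
    if orientation not in ("5prime", "3prime"):
        raise ValueError("orientation must be '5prime' or '3prime'")
    shortest = min(len(cs) for cs in cluster_sets)
    if max_pos > shortest:
        raise ValueError(
            f"max_pos={max_pos} exceeds the shortest gene's window count ({shortest}); "
            "apply the length filter first"
        )
    m = np.zeros((len(cluster_sets), max_pos), dtype=bool)
    for g, cs in enumerate(cluster_sets):
        m[g] = cs.flags[:max_pos] if orientation == "5prime" else cs.flags[::-1][:max_pos]
    return m


def positional_profile(
    cluster_sets: list[ClusterCallSet],
    orientation: str,
    max_pos: int,
    null_cluster_sets: list[list[ClusterCallSet]],
    nonterminal_from: int = 51,
    nonterminal_to: int = 200,
) -> PositionalEnrichmentProfile:
    """Per-position percent of genes flagged, versus null replicates.

    Position k counts from the start codon (5prime) or back from the final
    scored window (3prime; position 1 = last window). The non-terminal
    average is reported over 5' positions ``nonterminal_from..nonterminal_to``
    (at least 50 windows from both termini for genes passing the 250-window
    filter), with its SD across positions.
    """
    m = _terminal_flag_matrix(cluster_sets, orientation, max_pos)
    pct = m.mean(axis=0) * 100.0
    null_pcts = np.array(
        [
            _terminal_flag_matrix(rep, orientation, max_pos).mean(axis=0) * 100.0
            for rep in null_cluster_sets
        ]
    )
    if len(null_pcts) == 0:
        null_mean = np.full(max_pos, np.nan)
        null_sd = np.full(max_pos, np.nan)
    else:
        null_mean = null_pcts.mean(axis=0)
        null_sd = null_pcts.std(axis=0, ddof=1) if len(null_pcts) > 1 else np.full(max_pos, np.nan)
    # sigma is the across-replicate SD of the per-position percent; where that
    # SD vanishes (few replicates, or a null rate so low no replicate flags
    # the position) fall back to a binomial SE from the pooled null rate,
    # floored at one flag in the whole null ensemble.
    n_genes = len(cluster_sets)
    z = np.full(max_pos, np.nan)
    if len(null_pcts) > 0:
        pooled = float(null_pcts.mean()) / 100.0
        floor = 1.0 / max(n_genes * len(null_pcts), 1)
        pb = min(max(pooled, floor), 1.0 - floor)
        se_binom = 100.0 * np.sqrt(pb * (1.0 - pb) / n_genes)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(
                np.nan_to_num(null_sd) > 0,
                (pct - null_mean) / null_sd,
                (pct - null_mean) / se_binom,
            )
    nt_mean = nt_sd = None
    if max_pos >= nonterminal_from:
        hi = min(max_pos, nonterminal_to)
        if orientation == "5prime":
            seg = pct[nonterminal_from - 1 : hi]
            nt_mean = float(seg.mean())
            nt_sd = float(seg.std(ddof=1)) if len(seg) > 1 else None
    return PositionalEnrichmentProfile(
        orientation=orientation,
        position=np.arange(1, max_pos + 1),
        pct_genes=pct,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        n_genes=len(cluster_sets),
        n_null_reps=len(null_cluster_sets),
        nonterminal_mean=nt_mean,
        nonterminal_sd=nt_sd,
    )


def classify_terminal_genes(
    cluster_sets: list[ClusterCallSet],
    ranges: tuple[tuple[str, int, int], ...] = DEFAULT_TERMINAL_RANGES,
) -> pd.DataFrame:
    """Count genes with >= 1 flagged window inside each terminal range.

    Ranges are (name, start, end) in window coordinates from each terminus;
    the same ranges are evaluated from the 5' and the 3' side. Counts are
    reported with their explicit denominator (the number of qualifying
    genes), since percentages without denominators are ambiguous.
    """
    n = len(cluster_sets)
    rows = []
    for side in ("5prime", "3prime"):
        for name, start, end in ranges:
            count = 0
            for cs in cluster_sets:
                flags = cs.flags if side == "5prime" else cs.flags[::-1]
                if flags[start - 1 : end].any():
                    count += 1
            rows.append(
                {
                    "side": side,
                    "range": name,
                    "start_window": start,
                    "end_window": end,
                    "n_genes_with_cluster": count,
                    "n_genes_total": n,
                    "pct": 100.0 * count / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def null_cluster_sets(
    orfeome: list[ORFRecord],
    table: CodonUsageTable,
    n_reps: int,
    seed: int,
    tau: float = DEFAULT_TAU,
    window: int = 18,
) -> list[list[ClusterCallSet]]:
    """Cluster calls for weighted reverse-translation replicates, computed on
    the flat encoding (fast path used for null profiles)."""
    enc = EncodedOrfeome.from_orfeome(orfeome, window)
    woff = enc.window_offsets
    out = []
    for rep in range(n_reps):
        idx = resample_weighted(enc.idx, table, gene_rng(seed, rep, 0))
        vals = window_values_flat(enc, idx, table)
        with np.errstate(invalid="ignore"):
            flags_all = np.where(np.isnan(vals), False, vals <= tau)
        rep_sets = []
        for g, gid in enumerate(enc.gene_ids):
            flags = flags_all[woff[g] : woff[g + 1]]
            rep_sets.append(ClusterCallSet(gid, tau, flags, _intervals_from_flags(flags)))
        out.append(rep_sets)
    return out


def clusters_to_frame(cluster_sets: list[ClusterCallSet], profiles: list[MinMaxProfile] | None = None) -> pd.DataFrame:
    """BED-like interval table: gene_id, start_window, end_window, min_value."""
    by_gene = {p.gene_id: p for p in profiles} if profiles else {}
    rows = []
    for cs in cluster_sets:
        for start, end in cs.intervals:
            minv = np.nan
            p = by_gene.get(cs.gene_id)
            if p is not None:
                minv = float(np.nanmin(p.values[start - 1 : end]))
            rows.append(
                {
                    "gene_id": cs.gene_id,
                    "start_window": start,
                    "end_window": end,
                    "min_value": minv,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "start_window", "end_window", "min_value"])
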