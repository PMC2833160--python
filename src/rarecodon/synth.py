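"""Synthetic ORFeomes with planted rare codon cluster topology.

The generator emulates the statistical structure the terminal-enrichment
analysis assumes, with exact recorded ground truth:

* a skewed codon usage table (softmax over within-family ranks; skew 0 is
  uniform, large skew gives one dominant codon per family);
* genes of uniform random length (all passing the 250-window filter by
  default) whose codons are drawn from the table — under which spontaneous
  rare windows are vanishingly rare at the default skew, so every cluster
  present is a recorded plant;
* 5'/3' terminal plants: with probability q5 (q3) the first (last) scored
  window is made a run of each amino acid's rarest codon, guaranteeing a
  %MinMax of -100 at that terminal window;
* interior "background" bursts — the same rarest-codon runs dropped at
  random interior positions at an intensity calibrated (by a generate-
  measure-regenerate pass) so the mean per-position cluster rate over
  window positions 51..200 matches the requested background rate p. Bursts
  are kept >= 17 windows away from the scored terminal 50-window ranges so
  the terminal rates remain exactly q5 and q3;
* binary signal-sequence labels associated with the 5' plant through a
  relative risk, correlated secretion labels, functional-category strings,
  per-experiment Cy5/Cy3 expression ratios, and a two-group dG model in
  which the with-cluster population is rigidly shifted by delta kcal/mol.

Start codons are fixed at ATG and no internal stops are ever emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._codes import CODON_INDEX, CODONS, synonymous_families
from ._encoded import EncodedOrfeome, resample_weighted, window_values_flat
from .orfeome import CodonUsageTable, ORFRecord, n_windows

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_usage_table",
    "generate_orfeome",
    "generate_deltaG",
    "write_annotations",
    "write_truth",
]

DEFAULT_CATEGORIES = (
    "hypothetical",
    "energy metabolism",
    "amino acid biosynthesis",
    "nucleotide biosynthesis",
    "transport",
    "regulation",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic ORFeome.

    Defaults mirror the E. coli topology the analysis targets: terminal
    cluster rates q5/q3 of 8.5%/4.6%, a 2.3% non-terminal background, and a
    0.3 kcal/mol dG offset between the with- and without-cluster groups
    (medians near -5.6 vs -5.9 kcal/mol).
    """

    n_genes: int = 2000
    length_min: int = 268          # codons; >= 268 keeps every gene past the filter
    length_max: int = 600
    skew: float = 1.5              # usage-table unevenness (softmax rank weight)
    background_rate: float = 0.023  # p: per-position cluster rate, positions 51..200
    q5: float = 0.085              # P(cluster at 5' window 1)
    q3: float = 0.046              # P(cluster at final scored window)
    terminal_run: int = 18         # codons per planted terminal run
    window: int = 18
    tau: float = -10.0
    signal_frac: float = 0.18      # marginal P(signal sequence)
    signal_rr: float = 1.3         # relative risk of signal given a 5' plant
    secreted_given_signal: float = 0.8
    secreted_base: float = 0.05
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    expr_n_experiments: int = 8
    expr_log_mu: float = 0.42      # ln Cy5/Cy3 gene-mean distribution
    expr_log_sd: float = 0.45
    expr_rep_sd: float = 0.2
    dg_mean: float = -5.9          # kcal/mol, without-cluster group
    dg_sd: float = 1.2
    dg_shift: float = 0.3          # delta added to the with-cluster group
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Recorded ground truth of one generated ORFeome."""

    five_prime_planted: np.ndarray      # bool per gene
    three_prime_planted: np.ndarray     # bool per gene
    interior_windows: dict[str, list[int]]  # gene -> guaranteed-flagged window positions
    rates: dict[str, float]             # p, q5, q3 as requested
    calibrated_burst_rate: float        # per-position burst intensity used
    dg_shift: float
    labels: pd.DataFrame                # gene_id, signal, secreted, category, expr means
    usage_table: CodonUsageTable = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "rates": self.rates,
            "calibrated_burst_rate": self.calibrated_burst_rate,
            "dg_shift": self.dg_shift,
            "five_prime_planted": self.five_prime_planted.astype(int).tolist(),
            "three_prime_planted": self.three_prime_planted.astype(int).tolist(),
            "interior_windows": self.interior_windows,
        }


def generate_usage_table(skew: float, seed: int) -> CodonUsageTable:
    """Softmax-rank usage table: family frequencies proportional to
    exp(-skew * rank) with ranks assigned randomly within each family.

    skew 0 gives uniform families (X_min = X_avg = X_max = 1/n); a 2-codon
    family at skew s has frequencies (sigmoid(s), 1 - sigmoid(s)).
    """
    if skew < 0:
        raise ValueError("skew must be >= 0")
    rng = np.random.default_rng(seed)
    fams = synonymous_families("standard")
    freq: dict[str, float] = {}
    for aa in sorted(fams):
        cs = fams[aa]
        ranks = rng.permutation(len(cs))
        w = np.exp(-skew * ranks)
        p = w / w.sum()
        for c, pi in zip(cs, p):
            freq[c] = float(pi)
    return CodonUsageTable(freq=freq)


def _rarest_codon_by_aa(table: CodonUsageTable) -> np.ndarray:
    """64-long map codon index -> rarest synonymous codon index of its family."""
    fams = synonymous_families(table.genetic_code_id)
    out = np.arange(64, dtype=np.int64)
    for aa, cs in fams.items():
        rare = min(cs, key=lambda c: (table.freq[c], c))
        for c in cs:
            out[CODON_INDEX[c]] = CODON_INDEX[rare]
    return out


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _check_feasible(table: CodonUsageTable, tau: float) -> None:
    fams = synonymous_families(table.genetic_code_id)
    multi = [aa for aa, cs in fams.items() if len(cs) > 1]
    aa = multi[0]
    rare = min(fams[aa], key=lambda c: table.freq[c])
    if table.x_avg[aa] - table.x_min[aa] <= 0 or tau < -100:
        raise ValueError(
            f"infeasible synthetic spec: a window of rarest codons scores "
            f"above tau={tau} (skew too low to realize the threshold)"
        )


def _generate_codons(
    spec: SyntheticSpec,
    table: CodonUsageTable,
    lengths: np.ndarray,
    five: np.ndarray,
    three: np.ndarray,
    burst_rate: float,
    seed_key: int,
) -> tuple[np.ndarray, np.ndarray, dict[int, list[int]]]:
    """Draw the concatenated codon-index array with plants applied.

    Returns (idx, offsets, interior core windows per gene index)."""
    W = spec.window
    rng_aa = _spawn(spec.seed, seed_key, 0)
    rng_codon = _spawn(spec.seed, seed_key, 1)
    rng_burst = _spawn(spec.seed, seed_key, 2)
    fams = synonymous_families("standard")
    aas = sorted(fams)
    rep = np.array([CODON_INDEX[fams[aa][0]] for aa in aas], dtype=np.int64)
    rarest = _rarest_codon_by_aa(table)
    met = CODON_INDEX["ATG"]

    total = int(lengths.sum())
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    aa_draw = rng_aa.integers(len(aas), size=total)
    idx = rep[aa_draw]
    idx = resample_weighted(idx, table, rng_codon)
    idx[offsets[:-1]] = met  # start codons

    run = spec.terminal_run
    interior: dict[int, list[int]] = {}
    for g in range(len(lengths)):
        n = int(lengths[g])
        a, b = offsets[g], offsets[g + 1]
        if five[g]:
            idx[a : a + run] = rarest[idx[a : a + run]]
            idx[a] = met
        if three[g]:
            # final scored window covers codons n-W .. n-1 (1-based)
            lo = b - 1 - W  # 0-based global index of codon n-W
            idx[lo : lo + run] = rarest[idx[lo : lo + run]]
        # interior bursts: run codons [s, s+17] (1-based s) with all affected
        # windows inside positions [51, n_windows - 50]
        s_lo, s_hi = 68, n - 85  # 1-based inclusive bounds on burst start
        n_allowed = s_hi - s_lo + 1
        if burst_rate > 0 and n_allowed > 0:
            k = rng_burst.poisson(burst_rate * n_allowed)
            cores = []
            for _ in range(k):
                s = int(rng_burst.integers(s_lo, s_hi + 1))
                idx[a + s - 1 : a + s - 1 + run] = rarest[idx[a + s - 1 : a + s - 1 + run]]
                cores.append(s)  # window starting at codon s is fully planted
            if cores:
                interior[g] = sorted(set(cores))
    return idx, offsets, interior


def _interior_rate(
    idx: np.ndarray, offsets: np.ndarray, table: CodonUsageTable, spec: SyntheticSpec
) -> float:
    """Mean cluster rate over 5' window positions 51..200."""
    enc = EncodedOrfeome(idx=idx, offsets=offsets,
                         gene_ids=[str(g) for g in range(len(offsets) - 1)],
                         window=spec.window)
    vals = window_values_flat(enc, idx, table)
    woff = enc.window_offsets
    flags = np.zeros((enc.n_genes, 150), dtype=bool)
    with np.errstate(invalid="ignore"):
        f = np.where(np.isnan(vals), False, vals <= spec.tau)
    for g in range(enc.n_genes):
        flags[g] = f[woff[g] + 50 : woff[g] + 200]
    return float(flags.mean())


def generate_orfeome(spec: SyntheticSpec) -> tuple[list[ORFRecord], SyntheticTruth]:
    """Generate an ORFeome plus exact ground truth.

    Deterministic given ``spec.seed``. Raises if the requested cluster rates
    cannot be realized at the requested tau (e.g. skew 0, where every window
    scores 0).
    """
    for name, v in (("background_rate", spec.background_rate), ("q5", spec.q5), ("q3", spec.q3)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if spec.length_min < spec.window + 1:
        raise ValueError("length_min must exceed the window size")
    table = generate_usage_table(spec.skew, seed=spec.seed)
    if spec.q5 > 0 or spec.q3 > 0 or spec.background_rate > 0:
        _check_feasible(table, spec.tau)
        if spec.skew == 0:
            raise ValueError("infeasible: skew 0 makes every window score 0 > tau")

    rng_len = _spawn(spec.seed, 1)
    rng_plant = _spawn(spec.seed, 2)
    lengths = rng_len.integers(spec.length_min, spec.length_max + 1, spec.n_genes)
    five = rng_plant.random(spec.n_genes) < spec.q5
    three = rng_plant.random(spec.n_genes) < spec.q3

    # calibrate the interior burst intensity: generate at a pilot rate,
    # measure the realized positions-51..200 rate, rescale, regenerate.
    burst_rate = 0.0
    if spec.background_rate > 0:
        pilot = spec.background_rate / 20.0  # ~20 flagged windows per burst
        n_pilot = min(spec.n_genes, 1500)
        idx_p, off_p, _ = _generate_codons(
            spec, table, lengths[:n_pilot], five[:n_pilot], three[:n_pilot],
            pilot, seed_key=90,
        )
        measured = _interior_rate(idx_p, off_p, table, spec)
        if measured <= 0:
            raise ValueError(
                "infeasible: pilot bursts produced no clusters at tau="
                f"{spec.tau} (skew {spec.skew} too low)"
            )
        burst_rate = pilot * spec.background_rate / measured

    idx, offsets, interior = _generate_codons(
        spec, table, lengths, five, three, burst_rate, seed_key=91
    )

    gene_ids = [f"synth{g:05d}" for g in range(spec.n_genes)]
    labels = _draw_labels(spec, five)
    labels.insert(0, "gene_id", gene_ids)

    orfeome = []
    for g, gid in enumerate(gene_ids):
        gidx = idx[offsets[g] : offsets[g + 1]]
        seq = "".join(CODONS[k] for k in gidx)
        row = labels.iloc[g]
        orfeome.append(
            ORFRecord(
                gid,
                seq,
                labels={
                    "signal": bool(row["signal"]),
                    "secreted": bool(row["secreted"]),
                    "category": row["category"],
                    "expression_ratio": float(row["expression_mean"]),
                },
                _codon_idx=gidx,
            )
        )
    truth = SyntheticTruth(
        five_prime_planted=five,
        three_prime_planted=three,
        interior_windows={gene_ids[g]: ws for g, ws in interior.items()},
        rates={"p": spec.background_rate, "q5": spec.q5, "q3": spec.q3},
        calibrated_burst_rate=burst_rate,
        dg_shift=spec.dg_shift,
        labels=labels,
        usage_table=table,
    )
    return orfeome, truth


def _draw_labels(spec: SyntheticSpec, five: np.ndarray) -> pd.DataFrame:
    rng = _spawn(spec.seed, 3)
    q5_frac = five.mean() if len(five) else 0.0
    p0 = spec.signal_frac / (q5_frac * spec.signal_rr + 1 - q5_frac)
    p1 = min(spec.signal_rr * p0, 1.0)
    u = rng.random(len(five))
    signal = np.where(five, u < p1, u < p0)
    u2 = rng.random(len(five))
    secreted = np.where(signal, u2 < spec.secreted_given_signal, u2 < spec.secreted_base)
    category = rng.choice(list(spec.categories), size=len(five))
    gene_mean = np.exp(rng.normal(spec.expr_log_mu, spec.expr_log_sd, len(five)))
    reps = gene_mean[:, None] * np.exp(
        rng.normal(0.0, spec.expr_rep_sd, (len(five), spec.expr_n_experiments))
    )
    df = pd.DataFrame(
        {
            "signal": signal.astype(bool),
            "secreted": secreted.astype(bool),
            "category": category,
            "expression_mean": reps.mean(axis=1),
        }
    )
    for j in range(spec.expr_n_experiments):
        df[f"cy5_cy3_{j + 1}"] = reps[:, j]
    return df


def generate_deltaG(spec: SyntheticSpec, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-gene dG table (kcal/mol, nucleotides 1-40 analogue).

    Both groups sample the same base normal distribution; genes whose 5'
    plant falls in the first 13 windows (i.e. the planted terminal window)
    are shifted by ``dg_shift``, so group medians differ by about delta.
    """
    if not np.isfinite(spec.dg_shift):
        raise ValueError("dg_shift must be finite")
    rng = _spawn(spec.seed, 4)
    gene_ids = truth.labels["gene_id"].tolist()
    base = rng.normal(spec.dg_mean, spec.dg_sd, len(gene_ids))
    dg = base + np.where(truth.five_prime_planted, spec.dg_shift, 0.0)
    return pd.DataFrame({"gene_id": gene_ids, "dG": dg})


def write_annotations(truth: SyntheticTruth, path: str | Path) -> None:
    df = truth.labels.copy()
    df["signal"] = df["signal"].astype(int)
    df["secreted"] = df["secreted"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))
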