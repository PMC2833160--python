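# Methods

## The %MinMax window statistic

Codon usage frequencies are computed within synonymous families: for amino
acid *i*, X_ij is the fraction of its occurrences encoded by codon *j* in
the reference ORFeome, so each family sums to 1 and the family average
X_avg,i is 1/n. Stop codons never enter the table or the windows — the
statistic is defined over amino-acid-encoding codons only, and a terminal
stop codon is stripped on reading. An amino acid never observed in the
reference set receives uniform within-family frequencies (with a warning).

A window of W codons (default 18) is scored from the window sums A, V, Mx,
Mn of the actual, average, maximum and minimum family frequencies:
+100·(A−V)/(Mx−V) when A ≥ V, else −100·(V−A)/(V−Mn). The window-sum
formulation (rather than averaging per-codon ratios) is deliberate:
per-codon ratios are 0/0 for single-codon families (Met, Trp), while window
sums are always defined — Met/Trp simply contribute nothing to either
numerator or denominator. A degenerate denominator (a window of only
Met/Trp, or a fully uniform table) scores 0. Values are signed: negative is
%Min (rare-enriched), positive %Max.

**Window count convention.** A gene of n codons is scored at windows
1..n−W, window i covering codons i..i+W−1. This deliberately drops the last
full window (start n−W+1): the convention is chosen so that the 250-window
length filter corresponds to genes of ≥ 268 codons, matching the published
gene counts this analysis is designed to reproduce. The off-by-one (the
final codon belongs to no scored window) is recorded in the metadata
written by `gene_metadata`. Windows containing a non-ATGC base or an
internal stop codon are masked (NaN) and never flagged; only unmasked
windows count toward the length filter (a `count_masked` switch restores
raw counting).

**Numerics.** Scoring is vectorized with prefix sums over a concatenated
codon-index array (windows never span gene boundaries). Prefix-sum
subtraction reorders floating-point additions relative to a naive per-window
loop; the two agree to better than 1e-8 on the ±100 scale, and the test
suite pins that equivalence on 1,000 random genes.

## Cluster calls and threshold calibration

A window is part of a rare codon cluster when its value is ≤ τ (inclusive),
τ = −10 %Min by default. Maximal runs of flagged windows form cluster
intervals (1-based window coordinates). Per-organism calibration scans
candidate thresholds from the −10 default toward more stringent values
(−15, −20, … −60) and returns the least stringent candidate at which the
genome-wide count of windows ≤ τ exceeds the weighted-null expectation by
at least 3 null SDs (over ≥ 2 replicate randomized ORFeomes). The threshold
is only ever escalated, never relaxed below the default; an organism with
no significant candidate keeps −10 and is flagged `no-significant-threshold`.

## Randomization nulls

Both nulls preserve the encoded protein and gene length exactly.

* **Weighted random reverse translation** resamples every sense codon
  independently from its synonymous family with the usage-table
  probabilities. Aggregate codon usage of replicates converges to the input
  table; the per-position cluster rate is position-independent by
  construction, which is what makes it the null for terminal enrichment.
* **Dinucleotide-preserving shuffle** runs a Markov chain of synonymous
  moves — single-position synonymous substitutions and codon swaps between
  two positions encoding the same amino acid — accepting a proposal only if
  the local multiset of dinucleotides touching the changed codons is
  unchanged, which conserves all 16 genome-wide dinucleotide counts
  (including codon-boundary-spanning ones) exactly, and GC content as a
  corollary. Default 10 × gene-length proposals. Counts are conserved **per
  gene**, which is stricter than a per-genome constraint; a sequence with
  no accepted move (e.g. Met/Trp-only) is returned unchanged and logged.
  Typical accepted moves are third-position swaps between same-amino-acid
  positions whose right-neighbor nucleotides match.

**Seeding.** The public `randomize_orfeome` derives one stream per
(replicate, gene) from the master seed, so per-gene results are independent
of iteration order. The fast flat path used for 50-replicate null profiles
(`null_cluster_sets`) uses one stream per replicate over the concatenated
ORFeome; it is equally deterministic, but its draws are keyed to gene order
— the two paths give statistically identical, not bitwise identical,
replicates.

## Positional enrichment

For genes passing the ≥ 250-window filter, the profile reports the percent
of genes flagged at each window position counted from the start codon (5')
or backwards from the final scored window (3', position 1 = last window).
σ for the z-score is the across-replicate SD of the same per-position
percent over null ORFeomes (default 50 replicates). Where that SD is
exactly zero — common when the null rate is so low that no replicate flags
a position — the z denominator falls back to a binomial SE computed from
the pooled null rate, floored at one flag in the whole null ensemble; z is
then large but finite rather than undefined. The non-terminal average is
taken over 5' positions 51..200 (≥ 50 windows from both termini for every
gene passing the filter) and reported with its across-position SD.
Terminal-range counts (first/last 1, 25, 50; windows 101–150 and 151–200
from each terminus) are reported as counts **with explicit denominators**,
since percentages with implicit denominators are ambiguous.

## Contingency statistics

Gene-class enrichment uses Fisher's exact two-tailed test with the
dominant two-sided convention (sum of all tables with point probability ≤
the observed; scipy's implementation) — conventions differ in the third
decimal for some tables, so the choice is pinned by test. Degenerate tables
(an all-zero margin) return p = 1 with a warning. Per-codon regional usage
uses a χ² with Yates continuity correction on the 2×2 table of
(region count, interior count) × (group, rest) for each of the 61 sense
codons, reporting raw p (which drives interpretation), a Bonferroni column,
the enrichment direction, and an `unreliable` flag when any expected cell
is < 1. Expression strata average the per-experiment Cy5/Cy3 ratios per
gene and split at mean > 2.0 (high) and mean < 1.15 (low), both strict;
genes in between belong to neither stratum.

## 5' folding-energy comparison

dG values (kcal/mol, nucleotides 1–40) are consumed from a TSV; computing
them is delegated to an external RNA-folding engine and is out of scope.
Genes are grouped by whether any of windows 1–13 (the windows overlapping
nucleotides 1–40) is flagged. Both populations are binned on a shared
0.1 kcal/mol grid anchored at grid multiples (matching the offset step and
typical folding-engine output precision), per-bin counts are paired, and a
rigid offset swept from +2 to −2 kcal/mol in 0.1 steps is applied to the
with-cluster population before re-binning; R² at each offset is the squared
Pearson correlation of the paired counts. The reported quantity is the
signed shift applied to the with-cluster population at the R² maximum plus
its magnitude, which resolves the sign ambiguity inherent in quoting "an
offset" between two populations. The grid contains 0, so the best R² is
never below the unshifted R². The sweep is equivariant under shifting both
populations by any grid multiple.

## Synthetic data

The generator emulates the data structure the analysis assumes — a skewed
usage table, a length distribution clearing the filter, terminal cluster
rates q5/q3, a non-terminal background rate p, label structure, and a
two-group dG model — with exact recorded truth.

* **Usage table**: within each family, frequencies ∝ exp(−skew·rank) with
  ranks permuted per family by seed; a 2-codon family at skew s has
  frequencies (σ(s), 1−σ(s)). Default skew 1.5, at which windows drawn from
  the table itself essentially never reach −10 %Min spontaneously
  (empirical rate ~1e-5), so every cluster present is a recorded plant.
* **Plants**: a terminal plant replaces the first (last) W codons with each
  amino acid's rarest synonym, guaranteeing the terminal window scores
  exactly −100 ≤ τ; the start codon stays ATG. Interior background bursts
  are the same W-codon runs at random positions. Because windows overlap,
  a burst also drags neighboring windows below τ (the same smearing occurs
  in real data); burst starts are therefore confined ≥ 17 windows away
  from the terminal 50-window ranges, so the terminal rates stay exactly
  q5 and q3 and positions 1–50 / last 50 carry no background.
* **Background calibration**: the per-position burst intensity is set by a
  generate–measure–rescale pass (a ≤1,500-gene pilot is generated, the
  realized rate over positions 51..200 measured, and the intensity scaled
  proportionally). Across seeds the realized non-terminal rate is unbiased
  around the requested p with ~10% relative spread from burst-count Poisson
  noise.
* **Labels**: signal-sequence flags follow a two-point model with relative
  risk `signal_rr` given a 5' plant, holding the requested marginal
  fraction; secretion flags are correlated with signal flags; categories
  are uniform strings; expression ratios are lognormal per gene with
  replicate noise. dG values sample one normal distribution
  (mean −5.9, SD 1.2 kcal/mol), the with-cluster group rigidly shifted by
  `dg_shift` (default +0.3, giving medians near −5.6 vs −5.9).

What the generator does **not** emulate: real amino-acid composition
(uniform over the 20), real GC/dinucleotide structure beyond the skew
parameter, length-dependent codon bias, or the empirically decaying
enrichment over the first ~22 windows (plants produce a rectangular
terminal signal with smeared edges). Passing tests therefore demonstrate
correctness of the measurement machinery on data satisfying the model's
assumptions, not biological fidelity of any particular genome.

## Problem sizes and defaults

Parameter-recovery runs use 2,000 genes of 268–600 codons with 50 null
replicates; null-flatness checks use 400 genes × 20 replicates at skew 0.8
(where the spontaneous rate is non-trivial); the offset sweep is exercised
at 10,000 values per group; type-I calibration uses 1,000 simulated
2,262-gene label draws. These sizes keep the full suite under a minute of
compute while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Full-scale reproduction of the *E. coli* K12-MG1655 numbers (2,262 of
  4,288 genes past the filter, 66.8% with ≥ 1 cluster, 8.49%/4.60%/2.35%
  positional rates, dG medians −5.6/−5.9 with peak R² 0.7945 at offset
  magnitude 0.4) requires the original ORFeome release, SignalP/SecretomeP
  label tables and an external folding engine; the package consumes all of
  these as inputs and its class-enrichment tests reproduce the published
  p-values (0.0140, 0.4246) from the printed count tables.
* The dinucleotide shuffle is a constrained MCMC, not an exact uniform
  sampler over the conserved-count fiber; mixing is untested beyond the
  "changes ≥ 1 codon in ≥ 95% of seeds" property.
* The per-codon χ² tables inherit regional length imbalance between groups;
  raw p-values should be read jointly with the Bonferroni column.
* z-scores at positions where the null SD vanishes use the binomial
  fallback described above and should be read as "far beyond the null"
  rather than as calibrated normal deviates.
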