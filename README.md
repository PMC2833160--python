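# rarecodon

Rare codons — synonymous codons used less often than their family average —
are not scattered uniformly along bacterial genes: they cluster, and the
clusters pile up at the 5' and 3' ends of open reading frames, where
translational pausing can matter for secretion, co-translational folding and
ribosome traffic. `rarecodon` is a Python package for quantifying that
topology on any ORFeome (the complete set of coding sequences of an
organism), and for testing whether gene classes such as signal-sequence or
secreted proteins are enriched for terminal rare codon clusters.

The package is aimed at computational biologists studying codon usage,
translation kinetics and protein biogenesis, and at anyone who needs a
reproducible %MinMax implementation with proper randomization nulls.

## The statistic

Codon usage is summarized per amino acid *i* as the within-family frequency
X<sub>ij</sub> of codon *j*, with family average X<sub>avg,i</sub> (= 1/n for
an n-codon family), maximum X<sub>max,i</sub> and minimum X<sub>min,i</sub>.
For a sliding window of W = 18 codons, with window sums A = ΣX<sub>ij</sub>,
V = ΣX<sub>avg,i</sub>, Mx = ΣX<sub>max,i</sub>, Mn = ΣX<sub>min,i</sub>:

    %MinMax = +100 · (A − V) / (Mx − V)   if A ≥ V      (%Max)
              −100 · (V − A) / (V − Mn)   otherwise      (%Min)

+100 means the window uses each amino acid's most common codon, −100 the
rarest, 0 the organism's average usage. A window at or below a threshold
τ (−10 %Min by default) is a **rare codon cluster**. Per-position cluster
rates are compared against **weighted random reverse translations** (each
codon resampled from its synonymous family with usage-table probabilities)
and a **dinucleotide-preserving synonymous shuffle** (all 16 dinucleotide
counts conserved exactly), both of which preserve the encoded protein.
Gene-class enrichment is tested with Fisher's exact two-tailed test; 5'
mRNA folding-energy distributions are compared by a binned offset-sweep
regression.

## Worked example

Every stage runs on synthetic data with recorded ground truth — no
downloads. The generator plants terminal clusters at chosen rates
(defaults mirror an *E. coli*-like topology: 8.5% of genes starting and
4.6% ending with a cluster over a 2.3% background):

```python
from rarecodon import (SyntheticSpec, generate_orfeome, score_orfeome,
                       fisher_two_tailed)
from rarecodon.clusters import (call_orfeome_clusters, null_cluster_sets,
                                positional_profile)

spec = SyntheticSpec(n_genes=2000, seed=1)
orfeome, truth = generate_orfeome(spec)
profiles = score_orfeome(orfeome, truth.usage_table)     # %MinMax, W=18
sets = call_orfeome_clusters(profiles, tau=-10)          # cluster calls
nulls = null_cluster_sets(orfeome, truth.usage_table, 50, seed=1)
p5 = positional_profile(sets, "5prime", 250, nulls)
p3 = positional_profile(sets, "3prime", 250, nulls)
print(f"5' terminal: {p5.pct_genes[0]:.2f}% of genes (z = {p5.z[0]:.0f})")
print(f"3' terminal: {p3.pct_genes[0]:.2f}% of genes (z = {p3.z[0]:.0f})")
print(f"non-terminal background: {p5.nonterminal_mean:.2f}%")
```

prints

```
5' terminal: 9.20% of genes (z = 929)
3' terminal: 4.60% of genes (z = 650)
non-terminal background: 2.05%
```

— the planted rates recovered (9.20% and 4.60% are the realized plant
fractions at this seed), with terminal enrichment hundreds of null standard
deviations above the position-independent null. Class enrichment works from
plain counts; e.g. 172 of 454 signal-sequence genes versus 574 of 1808
others carrying a 5'-terminal-region cluster:

```python
>>> fisher_two_tailed(172, 282, 574, 1234).p_value
0.014020317910308475
```

The same analyses are available from the shell:

```bash
rarecodon simulate --n-genes 2000 --seed 1 --outdir sim/
rarecodon all --fasta sim/orfeome.fasta --annotations sim/annotations.tsv \
              --dg-table sim/dg.tsv --reps 50 --seed 1 --outdir run/
```

which writes the usage table, per-gene %MinMax profiles, cluster intervals
(BED-like TSV), positional enrichment profiles with z-scores, terminal-range
counts with explicit denominators, class-enrichment tables and the dG
offset-sweep summary, plus a manifest with parameters, seed and input
checksums.

## Layout

- `rarecodon.orfeome` — FASTA I/O, codon usage tables, the ≥250-window filter
- `rarecodon.minmax` — the %MinMax window statistic
- `rarecodon.nulls` — weighted reverse translation, dinucleotide shuffle
- `rarecodon.clusters` — cluster calls, threshold calibration, positional
  enrichment, terminal-range counts
- `rarecodon.stats` — Fisher/χ²(Yates) contingency tests, expression strata
- `rarecodon.structure` — 5' folding-energy offset-sweep regression
- `rarecodon.synth` — synthetic ORFeome generator with exact ground truth
- `rarecodon.pipeline`, `rarecodon.cli` — orchestration and the `rarecodon` CLI

See `docs/methods.md` for the model, parameter defaults and limitations.
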