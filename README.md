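# tcrshare

Quantitative comparison of T-cell receptor (TCR) repertoires, built for the
question of how many clonotypes two populations share and how that sharing is
distributed over abundant and rare clones. The motivating setting is the
comparison of CD4⁺ T-cell repertoires between regulatory-T-cell-deficient
(Scurfy) and healthy mice carrying a restricted TCRα repertoire, where
autoreactive clonotypes in the diseased strain turn out to be largely present —
but dormant — in healthy animals. The package covers the full desk side of that
analysis:

- **`tcrshare.repio`** — FASTA/FASTQ input (plain or gzipped), anchored
  extraction of TCRα CDR3 junctions from amplicon reads, translation, and
  AIRR-Rearrangement-style clonotype TSV I/O.
- **`tcrshare.repcore`** — the repertoire data model: replicate merging, the
  \>5-count abundance filter, frequencies, top-N dominance matrices,
  amino-acid-level collapsing ("N TCRs encoded by M nucleotide sequences"),
  shared-clonotype sets and TCR-set coverage.
- **`tcrshare.similarity`** — the Mutual Information Index (MII) overlap
  statistic and all-pairs MII matrices with within-/cross-group summaries.
- **`tcrshare.diversity`** — Rényi / Hill-number diversity profiles
  (effective number of species), with optional Good–Turing/Chao1
  unseen-species adjustment.
- **`tcrshare.sclink`** — a light single-cell stage: QC gates,
  log-normalization, Wilcoxon rank-sum marker genes with BH-FDR, and
  clonotype↔cluster linking across strains.
- **`tcrshare.synthgen`** — a synthetic-data generator that emulates the study
  design (3 mice/strain, 2 biological × 2 technical replicates, power-law
  clone sizes, tunable cross-strain sharing, small annotated single-cell
  datasets) and records exact ground truth for every estimate.

## The statistics

**Mutual Information Index.** Pool two repertoires with weights
(w_A, w_B); for clonotype frequency vectors p, q over the union let
m = w_A·p + w_B·q. With

&nbsp;&nbsp;I = Σ_c [ w_A·p(c)·ln(p(c)/m(c)) + w_B·q(c)·ln(q(c)/m(c)) ],&nbsp;
H_L = −(w_A ln w_A + w_B ln w_B),

the index is **MII = 1 − I/H_L**: 1 for identical abundance patterns, 0 for
disjoint repertoires. I is the mutual information between clonotype identity
and population label; with equal weights MII = 1 − JSD(p,q)/ln 2.

**Diversity profiles.** The Hill number of order q,
D_q = (Σ_i p_i^q)^{1/(1−q)} (with D_1 = exp of Shannon entropy, D_0 =
richness, D_∞ = 1/max p_i), is reported over a grid of orders. q < 1
emphasises rare clonotypes, q > 1 abundant ones, so two repertoires are
compared as whole profiles rather than by a single index.

## Worked example

`examples/02_repertoire_overlap.py` simulates the full two-strain study
design (75% shared clone identities, lognormal abundance jitter on shared
clones, 3 mice per strain, 4 replicates each), pools replicates per mouse,
applies the >5-count filter and computes all pairwise MIIs:

```
true (generating-distribution) MII between strains: 0.627

within- vs cross-strain MII (mean +/- SD over sample pairs):
strain_a strain_b comparison  n_pairs     mean       sd
      Sf       Sf     within        3 0.996284 0.000177
      Sf  healthy      cross        9 0.614047 0.001757
 healthy  healthy     within        3 0.994045 0.000223
```

Mice of the same strain sample the same clone distribution, so within-strain
MII sits near 1; cross-strain pairs recover the true between-strain overlap
(0.61 estimated vs 0.63 generating truth) — the qualitative pattern of a
shared-but-reweighted repertoire. The other example scripts demonstrate
clonotype extraction round trips, diversity profiles, dominance/coverage
analyses and the single-cell linking stage; each prints its results with a
note on how to read them.

A thin CLI mirrors the library (`tcrshare simulate | extract | tabulate |
filter | merge | mii | diversity | dominance | coverage | collapse-aa |
sc-qc | sc-normalize | sc-markers | sc-link`), e.g.

```sh
tcrshare simulate -o sim --seed 7
tcrshare mii --a sim/tables/Sf_m1_b1_t1.tsv --b sim/tables/healthy_m1_b1_t1.tsv
```

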