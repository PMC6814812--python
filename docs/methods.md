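# Methods

## Clonotype extraction

The amplicon design fixes known sequence on both sides of the TCRα CDR3: the
3′ end of the Vα2 segment upstream and the Cα-proximal constant region
downstream. Extraction therefore locates the two anchors and takes the
subsequence strictly between them; no germline alignment or Cys/FGxG motif
calling is attempted, because in a fixed Vα2/Jα context the anchors fully
define the junction. Anchor matching is Hamming distance with a
lowest-mismatch-then-leftmost tie-break and a default budget of 1 mismatch
per anchor — enough to tolerate a typical PE250 substitution error inside an
18-nt anchor without promiscuous matching. If the forward strand fails, the
reverse complement is searched (`search_both_strands`, on by default).
Degenerate reads (missing anchor, anchors out of order, empty junction) are
`NO_MATCH` data, not errors.

Translation is standard-code, frame 0. A junction whose length is not a
multiple of 3, that contains an ambiguous base, or whose translation contains
a stop codon anywhere is flagged `NONPRODUCTIVE`: the CDR3 sits mid-protein,
so a "terminal" stop is as disruptive as an internal one. Nonproductive
clonotypes are kept at the nucleotide level and excluded (with a logged read
count) when collapsing to the amino-acid level.

Clonotype identity defaults to `(cdr3_nt, v_call, j_call)`. Cross-strain
sharing is assessed at the amino-acid level by default — synonymous
nucleotide variants of one CDR3 protein sequence are one TCR, with the
variant multiplicity reported separately — because convergent recombination
makes nucleotide-level cross-individual identity the exception.

## Repertoire statistics

**Abundance filter.** Clonotypes observed more than `tau` times (default 5,
strict inequality) are retained; the filter is applied after replicate
merging, so the threshold refers to a population per organ and mouse rather
than to a single sequencing run. Frequencies are computed on the post-filter
repertoire. Both choices are exposed (`tau`, call order) since reasonable
pipelines differ here.

**Mutual Information Index.** Computed in nats via
I = H(m) − w_A·H(p) − w_B·H(q) over the clonotype union with 0·ln 0 := 0,
normalized by the label entropy H_L and subtracted from 1. The index is
base-invariant (the base cancels in I/H_L) and, with equal weights, equals
1 − JSD(p, q)/ln 2. Equal mixture weights are the default: they reproduce
the 0/1 boundary semantics independent of sequencing depth. Depth-weighted
mixtures are available but not default. A Miller–Madow variant corrects each
plug-in entropy by (K−1)/(2n) with that distribution's own support size and
read count (the mixture uses n_A + n_B); it is offered because small
repertoires bias the plug-in MII downward, but the plug-in form is the
default for reproducibility. Values are clipped to [0, 1] only within 1e-15
of the boundaries; anything further out would indicate a bug, not noise.

**Diversity.** D_q = (Σ p_i^q)^{1/(1−q)} with the Shannon limit at q = 1 and
D_∞ = 1/max p_i. The default grid {0, 0.25, 0.5, 1, 2, 4, ∞} spans the
rare-weighted (q < 1) and abundance-weighted (q > 1) regimes. Both H_q and
D_q are emitted, since published profile plots are ambiguous about which is
on the y-axis. The optional unseen-species adjustment (off by default, so
plug-in results are exactly reproducible) implements Good–Turing coverage
Ĉ = 1 − f1/n, rescales observed frequencies to Ĉ·p_i, and spreads the
residual mass 1 − Ĉ uniformly over f0 = ⌈Chao1 − S⌉ imputed unseen
clonotypes with Chao1 = S + f1(f1−1)/(2(f2+1)). This yields a proper
distribution whose D_0 is Chao1-scale richness. It is a deliberate, simple
completion of "consider unseen species": the uniform split of unseen mass is
an assumption, and profiles at large q are essentially insensitive to it.
An all-singleton sample (Ĉ = 0) falls back to plug-in with a warning.

**Dominance and coverage.** The dominance matrix looks up the reference
repertoire's top-N clonotypes (default N = 50, ties broken lexicographically
by nucleotide sequence for determinism) in each sample, 0 when absent.
TCR-set coverage is the summed frequency of a repertoire's clonotypes whose
identity key lies in a query set — the statistic behind "autoreactive TCRs
account for X% of sequenced CDR3s".

## Single-cell stage

Input is a genes × cells integer matrix with per-cell cluster labels and
optional per-cell CDR3 assignments; clustering and embedding are consumed,
not computed. QC applies the gene filter first (detected in ≥ 3 cells), then
cell filters on the reduced matrix: detected-gene count within [200, 2500]
inclusive, and mitochondrial read fraction at most `max_mito_fraction`. The
default for that cap is the literal printed pipeline value 0.05% (5e-4),
which is anomalously strict next to the conventional 5%; it is exposed as a
config key and deliberately excluded from any quantitative guarantee.
Normalization is ln(1 + c·sf/total) with sf = 10 000, so per cell
Σ expm1(value) = sf exactly and the transform is depth-invariant.

Marker detection is one-vs-rest per cluster: genes detected in ≥ 25% of the
cluster or of the rest are eligible (boundary inclusive), tested with the
two-sided asymptotic Wilcoxon rank-sum test with continuity correction on
normalized values, BH-FDR within each cluster, log2 fold change on mean
de-logged expression with a +1 pseudocount. Clusters under 3 cells are
skipped with a warning. Under a simulated global null the test's p < 0.05
rate is calibrated (checked at 5% ± 2% over ~200 genes in the suite).

Clonotype linking collapses per-cell CDR3s to the amino-acid level and
reports clonotypes present in every strain dataset: variant multiplicity,
cells per strain, and the headline "N TCRs, M nucleotide sequences,
K cells: k1 + k2" totals. The clonotype × cluster cross-tab conserves the
number of cells annotated with both labels.

## Synthetic data

Clone sizes follow a power-law rank-abundance model p_i ∝ i^(−α) (α = 1 by
default); the seed permutes clone labels only. A strain pair shares
round(ρ·n_clones) clone identities (ρ = 0.75, i.e. ~25% strain-private);
the second strain draws its own rank assignment, then shared clones are
overridden with the first strain's frequency times lognormal noise
exp(N(0, σ²)) and renormalized. σ = 1.5 was fixed once so that, under the
25%-private condition, the true MII of a generated pair falls mid-way in the
0.3–0.7 overlap band the analysis is designed to resolve (measured
0.55–0.64 over seeds 0–5). Cohorts draw 3 mice/strain × 2 biological × 2
technical replicates of 25 000 multinomial reads each — a deliberately
desk-scale stand-in for the millions-of-reads regime, chosen so the full
suite runs in seconds while leaving multinomial noise visible. Reads are
v_anchor + CDR3 + j_anchor with iid substitution errors (default 1e-3, and
exactly invertible at 0). CDR3s are stop-free by construction, 4–10 codons,
and rejected if they contain an anchor substring.

Ground truth (true MII, true D_q profiles, shared-clone list) is evaluated
exactly on the generating frequency vectors with the same closed forms the
estimators target — the truth computation shares no code path with the
count-based estimation being validated beyond those closed-form definitions,
and the test suite separately checks the closed forms against brute-force
joint-distribution evaluation and against R `vegan::renyi` values frozen
into the tests.

Single-cell simulation: negative-binomial counts (dispersion r = 2) around
per-gene lognormal base rates, mean depth 5000, 2000 genes, 600 cells in 3
equal clusters — roughly the detected-genes-per-cell regime of a small 10x
run. Marker genes (20 per cluster) are up-shifted by 2^log2fc (default
4-fold) in their cluster; `marker_log2fc = 0` produces an exchangeable-cells
null for calibration. Ten "mt-*" genes at trace expression serve the mito
gate, and a few QC-bait cells (sparse ~150-gene cells, mito-heavy cells) are
appended with recorded barcodes to exercise the filters. What the generator
does **not** emulate: V(D)J recombination biology, UMI/barcode error,
quality-score structure, dropout beyond NB sampling, batch effects, or
cross-cluster covariance — so passing tests demonstrate correctness of the
statistics under the stated model, not robustness to every artefact of real
libraries.

## Numerical conventions

Natural logarithms internally everywhere; 0·ln 0 := 0; MII clipping window
1e-15; Shannon limit used for |q − 1| ≤ 1e-9; q = ∞ handled symbolically.
Determinism: every stochastic routine takes an explicit seed (cohorts spawn
child seeds via `numpy.random.SeedSequence`), ties in rankings are broken
lexicographically, and table output is sorted, so identical config + seed
reproduces outputs byte-for-byte.

## Known limitations

- The MII has no analytic variance here; confidence intervals (e.g. by
  read subsampling) are future work.
- The unseen-species adjustment is a pragmatic completion, not an attempt to
  match any particular published estimator; q ≈ 0 values under adjustment
  inherit Chao1's lower-bound character.
- Anchored extraction assumes the amplicon design; it is not a general
  V(D)J aligner and does not handle indels inside anchors.
- The single-cell stage trusts upstream cluster labels and per-cell
  clonotype calls; doublets and label noise propagate into the linking
  report.
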