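# Methods

This note records the models, parameter choices and numerical decisions
behind `erv-regnet`, and what the synthetic-data experiments do and do
not demonstrate.

## Cell-type-specificity score

The score measures how closely a feature's expression profile across a
cell-type series matches a declared model profile. The pipeline is fixed:

1. per-cell CP10k normalization (counts scaled to 10,000 per cell), then
   log2(x+1);
2. per-feature Z standardization across all cells of the dataset being
   scored, with population SD (ddof = 0);
3. mean Z per cell type, then min-max rescaling of the means to [0, 1],
   giving the data profile `d`;
4. `SSR = Σ_c (d_c − m_c)²` against the model weights `m`, and
   score = −log10(max(SSR, 1e-12)).

Choices worth making explicit:

* **Scoring is confined to the model's cell types.** When a matrix mixes
  datasets (a germ-cell induction series plus an ESC comparison), cells
  outside the modelled series are excluded before standardization, so a
  feature's behaviour in unrelated cell types cannot distort its score.
* **SSR floor.** A perfect profile match gives SSR = 0; the 1e-12 floor
  maps it to a finite score of 12.0 while preserving the ranking, which
  equals the ranking by −SSR exactly.
* **Degenerate features.** Zero-variance features (no expression
  anywhere) and features whose per-type means are all equal (rescaling
  undefined) are flagged and excluded from scoring rather than scored
  arbitrarily; the "top 10%" cut is taken over the scored universe.
* **Ties at the top-fraction cutoff are included**, so the realized
  fraction can exceed the nominal one; it is reported alongside.

The score is invariant to per-cell library size (CP10k) and to
feature-wise affine transforms of log expression (Z score); both
invariances are asserted in the test suite.

## Upregulation calling

Features upregulated in the naïve state are those with log2FC > 1 at
FDR < 0.05 against the primed state, after removing features whose 90th
percentile of reads-per-million falls below 0.2. Two engines sit behind
the same table contract (`log2fc`, `p`, `fdr`, group means):

* **Wald (default):** a negative-binomial GLM per feature (DESeq2 model
  via pydeseq2) with `poscounts` size factors. The bulk median-of-ratios
  estimator discards every gene containing a zero count in any sample;
  on sparse single-cell matrices only the highest-expressed genes
  survive, which measurably distorts the factors (we observed a 1.9×
  inflation absorbing half of a planted 4× effect), so the
  positive-counts variant is used.
* **Rank stand-in:** Wilcoxon rank-sum on log2[CP10k+1] with the fold
  change computed from group means of CP10k with a pseudocount of one.
  The pseudocount biases the fold toward zero for features with mean
  CP10k below ~1, which costs sensitivity at the log2FC > 1 threshold
  for weakly expressed features; the Wald engine does not share this
  bias. The stand-in remains available (`de_method: rank`) and any
  externally computed table can be supplied verbatim (adapter mode).

Classification then partitions features into `both` (top-fraction score
AND naïve-up), `pgclc_only`, `naive_only`, `other`. Manual
reclassifications are possible only as an explicit override list and are
marked in the output.

## Interval statistics

* **Permutation test.** Length-preserving uniform relocation, chromosome
  drawn with probability proportional to length, shuffled intervals may
  overlap each other, no exclusion regions. Overlap means ≥ 1 shared bp,
  strand-agnostic; counting is region-level (how many query regions hit
  any target). p is the upper Poisson tail P(X ≥ obs) at λ = mean
  permuted count; a zero λ is floored at 1/n_perm and flagged. With 100
  permutations the null fold has Monte-Carlo spread ≈ λ^(−1/2) per
  replicate; calibration is checked both per experiment (fold within
  [0.7, 1.4] at λ ≥ 20) and in aggregate (type-I rate ≤ 0.10 at nominal
  0.05 over 200 null replicates, mean fold within [0.9, 1.1]).
* **Proximity binomial test.** TSS windows are the symmetric extension
  [pos − w, pos + w); windows are merged within each gene set before
  measuring lengths or counting peaks, so a peak counts once per set. A
  window of 0 gives Li = 0 and an NA result with a warning.
* **Fisher tests.** Category×overlap tables use the sample odds ratio
  ad/bc and a two-tailed p; empty or universe-spanning categories give
  NA rows. Gene-set enrichment uses the one-tailed (greater)
  alternative, equal to the hypergeometric upper tail.
* **Distances.** A TSS inside a locus is at distance 0, otherwise the
  gap to the nearer end; gene-level distance is the minimum over the
  gene's transcript TSSs; adjacency is inclusive (≤ 50 kb by default,
  with a supported sweep over 20/50/100/200/500 kb).
* **Regulator calling** requires permutation enrichment (log2 fold > 2,
  FDR < 0.05, > 20 binding events) plus cell-state-specific expression:
  top-fraction specificity score (PGCLC route) or log2FC > 2 at
  FDR < 0.05 (naïve route), with mean log2[CP10k+1] > 0.4 in the
  relevant cell type in either route.

## Insertion dating

Loci ordered old→young by the subfamily phylogeny are scanned per
species with a 10-locus window; a window qualifies when ≥ 4 member loci
have an orthologous insertion (strictly more than 3 of 10; both numbers
configurable). Missing ortholog status counts as not-present — the
window exists precisely because missing values are common, and treating
missing as present would defeat it. The species boundary is the youngest
locus actually present within the youngest qualifying window; loci
strictly older are pre-divergence, the boundary locus itself is not
flagged. Anchoring on a present locus (rather than the window's edge)
keeps the call exact on complete data; the window's only role is to ride
over missing values. Branch labels resolve by the deepest pre-divergence
species (HCGOG > HCGO > HCG > HC > H); inconsistent flag combinations
are resolved the same way with a logged warning. Genes inherit the
branch of their associated loci, or `ND` when loci disagree or lack a
label. Macaque and marmoset flags are computed (they calibrate
contamination by older subfamilies) but produce no label beyond HCGOG.

Alignment hygiene before tree building: columns with < 85% non-gap
coverage are removed first, then sequences with > 15% gaps over the
remaining columns; leaves with standardized external branch lengths > 3
(sample SD) are discarded once, without iterating to convergence.
Results depend on the supplied locus order; any old→young order
consistent with the tree is accepted.

## Split-read polymorphism calling

Candidates are primary, soft-clipped alignments carrying an SA tag;
supplementary and secondary records are excluded, as are pairs whose two
segments map to different chromosomes. The two facing breakpoints (end
of the left segment, start of the right) must fall within 25 nt of the
element's left and right boundaries respectively — the segments flank
the element from opposite sides, the only configuration that spans the
empty insertion site. One read contributes at most one event per locus
and duplicate read ids collapse. A sample is called as lacking ≥ 1
allele at ≥ 2 skipping reads; calls are per sample, never pooled across
samples, and are monotone in the threshold by construction.

## Synthetic data

The generators reproduce the statistical structure the methods consume,
with planted truth for every caller:

* **Expression:** negative-binomial counts (variance m + m²/r, r = 2 by
  default; r → ∞ gives the Poisson limit) over eight cell types (six
  germ-cell stages plus naïve/primed ESC), 200 cells per type and 2,000
  genes by default. Baseline per-gene rates are lognormal(0, 1),
  normalized so a baseline cell averages `library_size` = 5,000 counts.
  Planted classes multiply the mean by `effect_size` = 4 in the
  signature cell types, with MLC at half effect, mirroring the model
  weight. Effects are applied without renormalizing, so activated cell
  types have correspondingly larger totals, as real cells do.
* **Genome:** non-overlapping TE loci per subfamily with
  reliability-score annotations, peak sets with an exact planted
  TE-overlap count, strand-aware TSSs; rejection sampling with a
  1000-try cap.
* **Ortholog history:** loci assigned to branches by proportion, ordered
  old→young, species presence following the branch, then masked to
  missing independently per cell.
* **Alignments:** junction-spanning soft-clipped records with SA tags at
  planted absent loci, plus noise reads clipped > 25 nt from any
  boundary. Read bases are arbitrary.

What passing on these data shows — and does not. The generators plant
clean multiplicative effects, independent cells, a single batch, no
doublets or ambient RNA, exact staircase ortholog histories and
error-free read positions. Recovery rates measured here are therefore
upper bounds on real-data performance: they validate the statistical
machinery (correct formulas, calibrated nulls, monotone thresholds,
determinism), not robustness to batch structure, contamination or
alignment artifacts.

## Problem sizes and determinism

Default synthetic sizes (1,600 cells × 2,000 genes; 180 TE loci; 200
dated loci; 20-sample cohorts with 50 loci) keep a full pipeline run
under a minute on one CPU while leaving planted effects well above the
detection thresholds. The pipeline expands one seed into independent
per-stage streams (so skipping a stage does not shift another's
randomness) and records content hashes of every written table; a rerun
with the same configuration is byte-identical.
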