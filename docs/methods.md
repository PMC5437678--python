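# Methods

This note documents the statistical procedures gbmscape implements, the
design choices that were genuinely open, the synthetic data model, and
what the tests do and do not establish.

## Coordinate and counting conventions

Intervals (BED, bedGraph, tiles, DMRs) are 0-based half-open; cytosine
positions are 1-based, as in per-cytosine bisulfite reports.  The single
1-based→0-based conversion happens inside count aggregation; a cytosine
at 1-based position p belongs to the tile containing 0-based p−1, so
position 101 falls in tile [100, 200).  Chromosome names are taken
verbatim with no aliasing; name-set mismatches are hard errors listing
the disjoint names.

Methylation levels are always *weighted*: pooled Σ#C / Σ(#C+#T) over the
cytosines of one context.  Plus- and minus-strand calls are summed with
no CG-dyad pairing.  The mean-of-ratios alternative (each covered
cytosine contributing equally) is exposed as an option on
`region_methylation` but used nowhere else; pooling is consistent with
Fisher testing on summed counts and down-weights barely covered
cytosines.  Levels of uncovered regions are missing (NaN), never 0.

## Hypo-DMR procedure

Parameters (`DmrParams`), with defaults:

| parameter | default | meaning |
|---|---|---|
| tile_size | 100 bp | genome bin width |
| min_calls | 20 | minimum C+T calls per tile per sample |
| fdr | 0.01 | BH-adjusted q threshold |
| min_delta | 0.20 | minimum absolute reduction (WT − kd level) |
| merge_gap | 200 bp | maximum edge-to-edge gap merged |
| n_required_reps | 2 | knockdown replicates that must each pass |

Choices made where the procedure admitted readings:

- **Fisher sidedness.** The per-tile test is two-sided; the
  hypomethylation direction is enforced separately by the δ ≥ 0.20
  filter.  A direction-agnostic p plus a signed effect filter selects
  hypomethylation without asserting a tail for the test itself.  The
  two-sided p sums the probabilities of all tables with the observed
  margins whose point probability is ≤ the observed one, with a 1e-7
  relative tolerance on the comparison to absorb floating-point noise in
  tied probabilities.  Degenerate tables (a zero margin) return p = 1.
- **BH universe.** The adjustment runs per replicate over that
  replicate's *tested* tiles only; coverage-filtered tiles are omitted
  entirely and do not count toward m.
- **"Absolute reduction"** is per tile per replicate on pooled tile
  counts: (WT level − kd level) ≥ 0.20, not a relative change.
- **Coverage filter scope.** By default the ≥ 20-calls rule applies to
  the WT/kd pair of each replicate comparison ("pair"); a stricter mode
  (`coverage_filter="all"`) requires it in every sample simultaneously.
- **Merging** is transitive with gap ≤ 200 (a gap of exactly 200 merges;
  adjacent and overlapping tiles always merge), so output regions are
  pairwise separated by more than 200 bp.
- **Region summary.** The reported region δ is recomputed from pooled
  counts over the *full merged span* (including any bridged gap tiles),
  with the knockdown replicates' counts summed; per-replicate per-tile
  statistics remain available via `call_dmrs(..., return_details=True)`.
  Because the span can include bridged tiles and WT/kd coverage weights
  differ, a region's pooled δ is typically, but not guaranteed to be,
  ≥ min_delta.  min_q is the smallest q among the region's selected
  tiles across replicates.
- **WT replication.** WT enters as a single (pooled) sample; the
  replicate-intersection rule applies to the knockdown only.

Both exact tests are computed in log space with lgamma-based binomial
coefficients.  The hypergeometric upper tail is accumulated from the top
of the support (smallest terms first), giving relative accuracy well
below 1e-6 even for tails near 1e-35 and populations of ~21,000.  The
Fisher and tail implementations are verified in the test suite against
exact integer/rational enumeration (exhaustively for margins ≤ 30 and
populations ≤ 60) and against scipy's independent implementations.

## Metagene profiling

Genes are mapped to upstream flank / body / downstream flank, each flank
scaled to the gene-body length L (so flanks span [start−L, start) and
[end, end+L)).  Defaults of 40 body bins and 20 flank bins are arbitrary
fixed choices — any binning preserves the qualitative shapes — and are
configurable everywhere.

Bin values use fractional base-to-bin overlap weights (each base's unit
interval is split across the ≤ 2 bins it overlaps).  This makes profiles
exactly equivariant under coordinate mirroring + strand flipping, which
integer floor-binning is not when the segment length is not a multiple of
the bin count.  Methylation bins pool counts within the bin and the
across-gene average is unweighted (every gene counts equally, the
standard metagene convention); coverage bins are mean per-base signal.
Minus-strand gene vectors are reversed so the axis runs 5′→3′.  Flank
bins extending past a chromosome end are missing, genes shorter than the
bin count are skipped with a warning, and empty groups produce missing
rows.

Quintiles are computed over genes with FPKM > 0.5 by default (the one
expression threshold the analysis defines); ties are broken by gene id
so the assignment is deterministic, group sizes differ by at most one,
and with fewer genes than groups the low quintiles fill first.

Differential profiles are element-wise kd − WT (`difference`) or
log2((kd+ε)/(wt+ε)) with ε = 1% of the global mean signal
(`log2_ratio`); both are provided because "relative" profiles admit
either reading.  Missing values propagate.  Coverage tracks carry a
`total_reads` denominator and `normalize_track` scales to counts per
million for cross-library comparison; the simulated tracks in the
examples are depth-matched by construction and are differenced raw.

## Synthetic data model

The generator samples, from one integer seed, everything the pipeline
consumes.  No nucleotide sequence exists: cytosine positions, strands and
contexts are drawn directly (per-base densities CG 0.04, CHG 0.03,
CHH 0.08), fixed once per genome and shared by all samples, as a real
genome would fix them.

- **Annotation.** 200 genes (1–4 kb) and 100 TEs (0.5–3 kb) packed
  without overlap, uniformly, on 2 × 500 kb chromosomes; FPKM is
  log-normal with a 10% zero fraction.  H3.3-enriched regions are the 3′
  two-thirds of genes in the top three expression quintiles, encoding the
  variant's TES-proximal, transcription-linked deposition.
- **Methylome.** Per cytosine, the true probability is 0.02 background;
  TE levels (CG 0.85, CHG 0.35, CHH 0.10) inside TEs in both conditions;
  and for genic CG, 0.9 · w(quintile) · relpos, where relpos runs 0→1
  from TSS to TES and the quintile weights (0.2, 0.5, 1.0, 1.0, 0.7)
  peak strictly before Q5 — gene-body methylation is highest over
  expressed, not the most highly expressed, genes.  The knockdown
  multiplies genic CG probabilities by 1 − loss(quintile) with
  loss = (0, 0.2, 0.4, 0.6, 0.8): loss grows with expression, Q1 is
  untouched, TEs and non-CG contexts are identical between conditions.
  Calls are Poisson(30) totals with Binomial methylated counts.
  `expected_gene_body_loss` returns the analytic planted effect
  (0.9 · w · ½ · loss per gene), the ground truth for recovery tests.
- **Chromatin tracks.** Per-base Poisson intensities: H1 is elevated
  intergenically and depleted over expressed bodies, with the knockdown
  adding a quintile-graded body gain (0.2–2.0 reads/base); H2A.Z has a
  5′ peak with a 3′-weighted, quintile-graded knockdown gain; H3K4me3
  (5′ peak) and H3K36me3 (body) are condition-invariant controls.
  Counts are drawn per 10-bp bin — a sum of per-base Poisson draws is the
  same Poisson, and files stay desk-scale.  The H1/H2A.Z gain magnitudes
  are order-of-magnitude choices, not reconstructions of measured effect
  sizes.

Randomness uses `SeedSequence(seed, spawn_key=(domain, index))` with
fixed domains (annotation / positions / methylome-sample / track), so
replicates are independent but reproducible and fixed configs give
byte-identical files.

What the generator does *not* emulate: sequence composition and real CG
spacing, bisulfite non-conversion and mapping errors, coverage biases,
chromatin-state autocorrelation beyond the annotation, partially
methylated domains, or any coupling between methylation and the
chromatin tracks beyond their shared expression dependence.  Passing
tests therefore demonstrate correctness of the *procedures* under the
declared generative model, not performance on real libraries.

## Problem sizes and test design

The default simulated genome (1 Mb, 200 genes, coverage 30) makes every
planted Q4/Q5 gene-body loss comfortably detectable, so the recovery
check (sensitivity and called-base precision ≥ 0.90 on the ~80 genes
with planted mean loss ≥ 0.25) is a sharp end-to-end functional test
that still runs in seconds.  Equivalence with the naive reference caller
uses 100 random ≤ 12-kb genomes with random coverage (0–40) and patchy
loss, deliberately including mostly-filtered and DMR-free genomes.  Null
behaviour (knockdown drawn from the WT distribution) is averaged over 20
seeds; with the δ ≥ 0.20 filter and two-replicate intersection the
selected fraction is essentially zero, far below the 0.02 budget.

## The pipeline's enrichment statistic

The study-scale enrichment (hypervariable genes among downregulated
genes) needs external gene lists, so the self-contained pipeline run
instead asks the analogous question of its own data: are DMR-overlapped
genes enriched among the top two expression quintiles?  Population = all
simulated genes, successes = Q4∪Q5 (of expressed genes), sample =
genes overlapped by ≥ 1 hypo-CG-DMR.  Under the default model this is
strongly significant; under the null configuration it is not computed
(no DMRs) and the summary reports NA rather than 0.

## Known limitations

- The caller tests each tile independently; no spatial smoothing or
  segmentation HMM, so single noisy tiles inside a long loss region can
  break a region in two (the 200-bp merge absorbs most such gaps).
- Fisher p-values on pooled counts treat reads as independent Bernoulli
  calls; overdispersion between biological replicates is handled only by
  the two-replicate intersection, not modelled.
- `overlap_fraction` is binary (≥ 1 bp); no minimum-overlap fraction
  variant is offered.
- Hyper-methylated regions are not called (the knockdown phenotype is
  loss); CHG/CHH DMRs run through the same machinery but carry no
  validated expectations.
- Metagene bins of very sparsely covered groups average few genes; the
  profiles report n_genes per group but no confidence bands.
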