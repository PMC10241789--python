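# Methods

This note documents the models and procedures implemented in `crestreg`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate conventions

All intervals are 0-based half-open (BED convention). Coordinates quoted in
1-based browser style — such as the HIRE1/HIRE2 landmark coordinates on
mm10 (`crestreg.landmarks`) — are converted on ingestion by subtracting one
from the start, so a 1-based inclusive span keeps its length
(end − start + 1). Chromosome names are compared by exact string equality;
no `chr` aliasing is performed, because silent normalization hides data
errors. Strand is carried through I/O but ignored by every overlap
operation; only TSS placement uses it implicitly.

## Super-enhancer calling

The caller follows the ROSE recipe: filter, normalize, stitch, rank, cut.

* **Promoter window**: TSS ± 2500 bp, implemented as the half-open window
  `[TSS−2500, TSS+2500)`. Peaks overlapping any such window, any blacklist
  interval, or chromosomes outside the allowed set are removed before
  stitching. Stitched regions whose *span* comes to overlap a promoter
  window are removed afterwards as well — a merged span can swallow a
  promoter that no constituent peak touches.
* **Stitching gap**: 12.5 kb, inclusive (`gap ≤ 12 500`). The boundary is
  measured from the running end of the region being built (the maximum end
  so far), which coincides with the previous peak's end for sorted,
  non-nested peaks and guarantees that output regions are separated by
  strictly more than the gap even for nested inputs. Stitching is
  idempotent on its output.
* **Signal**: counts per million (`raw / library_total × 1e6`) summed over
  constituent peaks per sample. CPM makes calls invariant to joint scaling
  of one sample's counts and total.
* **Cutoff**: with signals sorted ascending and both axes scaled to [0, 1],
  the cutoff rank is the smallest argmax of (scaled rank − scaled signal).
  For a convex ranked curve this is where a slope-1 line is tangent to the
  curve, i.e. the hockey-stick elbow. Ties go to the smallest index; SE
  membership requires signal *strictly* above the cutoff value; if all
  signals are equal nothing is called. The rule is deterministic and is
  verified against an exhaustive scan in the tests.
* **≥3-peak rule**: the cutoff is computed on all stitched regions, and the
  constituent-count filter is applied afterwards, so sparse high-signal
  regions influence the threshold but are never reported as SEs.
* The catalogue is the union of per-sample calls, keyed by interval.

## SE–promoter linking

A link (SE, gene, population) requires simultaneously: one interaction
record with score ≥ 5 (inclusive) from the gene's bait to a fragment
overlapping the SE; expression strictly above 2 RPKM; and SE activity.
"Active" means the SE's summed CPM in that population exceeds that
population's own hockey-stick cutoff — the calling module defines exactly
one per-sample threshold, so it is the natural activity boundary.

Link strength is the arithmetic mean score over **all** recorded
bait↔SE-fragment interactions, including sub-threshold ones; the ≥5
threshold gates link existence only. When no interaction is recorded the
mean is NaN, deliberately distinct from 0.

Relative values per population are `log2((x + 0.5) / (mean + 0.5))`; the
0.5 pseudo-count bounds the output for zero entries and cancels for
constant rows. Row clustering uses k-means (k = 7 by default) — k-means++
initialization, best of 10 restarts by within-cluster sum of squares,
deterministic under a fixed seed. The same rule backs every k-means in the
package (profiles k = 3, hit rates k = 2, motif similarity k = 10).

**Virtual 4C**: one track entry per distinct other-end fragment of the
bait, duplicate records summed, sorted by coordinate, emitted as bedGraph.
Total track signal equals the sum of the bait's record values.

**Genotype interaction change**: the two samples' raw-count vectors are
taken over the union of the bait's other-end fragments (absent fragments
imputed as 0), quantile-normalized against each other (each vector's sorted
values replaced by rank-wise means of the two sorted vectors; entries tied
within a vector receive the mean of the values their positions span), then
summed over fragments overlapping the target region; the statistic is
`100 × (1 − sum_b / sum_a)`. Tie-averaging is required for a well-defined
map on count data, at the price that the two sorted normalized vectors
coincide exactly only for tie-free inputs. A zero baseline sum is an error
(the percent change is undefined), not a 0 or 100.

## Motif discovery

* **Classification**: promoter peak iff the peak midpoint
  (`⌊(start+end)/2⌋`) is strictly less than 1 kb from the nearest TSS;
  everything else is an enhancer. Sex-chromosome peaks are excluded from
  the enhancer set because mixed-sex pools make their coverage
  uninterpretable; in the synthetic genome "autosomal" means any chromosome
  not named chrX/chrY.
* **Accessibility**: log2(CPM + 1), then centered by the per-peak row mean
  ("relative accessibility"); every relative row sums to zero.
* **Ranking**: Pearson correlation of each enhancer's relative row against
  each cluster's mean profile. Zero-variance rows get r = 0 to every
  profile (Pearson is undefined there; exclusion by default). Each enhancer
  is assigned to its argmax profile (ties to the lowest index) *before*
  ranking, which enforces disjoint top-N sets by construction; within a
  profile, ranking is by r descending with genomic coordinate order
  breaking ties. Residual peaks are the control set.
* **Enrichment**: per (motif, set), a 2×2 table of peaks with ≥1 hit vs
  without, set vs control; one-sided Fisher exact test in the enrichment
  direction; Benjamini–Hochberg FDR across all (motif, set) pairs; a motif
  is selected at FDR < 0.001 in any set. Presence/absence rather than hit
  counts keeps the table exact and robust to peak-length effects, which are
  handled separately by the per-kb hit rate.
* **Scanning**: PFM → probabilities with a 0.01 per-cell pseudocount →
  log2-odds against a uniform 0.25 background; every offset on both strands
  is scored; threshold 10.0 is an absolute log2-odds score. Windows
  containing any non-ACGT base score −∞. A numeric (non-percentage)
  threshold is treated as absolute because the score scale is then
  self-contained; log2 and uniform background are the package's fixed
  convention.
* **Similarity**: max Pearson correlation between flattened aligned
  probability columns over all ungapped offsets with ≥4 overlapping columns
  (full length for shorter motifs), including the reverse-complement
  orientation; D = 1 − S. Representatives: 1-D k-means (k = 2) on mean hit
  rates keeps the higher-rate cluster; k-means (k = min(10, n)) on the rows
  of D; per cluster, the medoid (least average distance to the other
  members, ties broken by lexicographic motif id).

## Expression utilities

RPKM = count / (gene length in kb) / (library total in millions). ΔΔCt:
ΔCt = Ct_target − Ct_reference, centered by the mean wild-type ΔCt,
relative expression 2^(−ΔΔCt); the wild-type geometric mean is exactly 1 by
construction. Primer-efficiency correction is not modeled; statistical
testing across genotypes is left to external tools.

## The synthetic-data generator

One integer seed feeds a root stream; each generator draws from a child
stream derived by a fixed spawn key, so adding a generator never perturbs
another, and a fixed seed reproduces every table bit for bit.

* **Genome/annotation**: 2 chromosomes × 10 Mb, 60 genes with one TSS each
  on a 20 kb grid, gene lengths 1–50 kb; restriction fragments tile each
  chromosome gap-free with exponential lengths (mean 4 kb, min 500 bp),
  emulating a HindIII map.
* **H3K27ac**: 300 peaks, of which 12 planted clusters of 3–5 peaks within
  stitching distance. Raw counts are log-normal (μ = 3, σ = 0.8) — chosen
  to give a convex ranked curve with a clear elbow — and cluster peaks are
  multiplied by 20 in one designated population (round-robin over
  FNP/Mx/Md/PA2). Background peaks are deliberately placed beyond stitching
  distance of everything else, so the planted clusters are the only
  multi-peak stitched regions and the planted truth is identifiable; a
  consequence is that the aggregate-signal advantage of *being a cluster*
  persists even at signal scale 1, so the meaningful null property is the
  disappearance of the designated-population boost, not chance-level
  recall. Recovery is scored on the called catalogue by exact interval
  identity.
* **Interactions**: background scores exponential(mean 1), making score 5 a
  meaningful boundary (null tail e⁻⁵ ≈ 0.7%); planted bait→SE-fragment
  links score 5 + exponential(mean 3) in the designated population and are
  clipped below 5 elsewhere (the construction must guarantee sub-threshold
  scores there); read counts are Poisson(2 + 3·score), giving the positive
  score–count correlation real capture data shows.
* **Expression**: log-normal background; planted-link genes at 5 +
  exponential(5) RPKM in their designated population and 0.5 elsewhere.
* **Accessibility**: 31 focus-region peaks plus 4000 background enhancers,
  two conditions × two replicates. Three planted profiles (up at the late
  condition, up at the early condition, flat) shift log2 signal by ±1.5;
  background rows get i.i.d. uniform(±1.5) per-sample effects plus
  N(0, 0.2) noise. The 4000-peak background keeps the top-1000 set
  construction and its residual control meaningful at desk scale (the real
  study had ~10⁵ enhancers).
* **Sequences**: i.i.d. uniform ACGT backgrounds of peak width with motif
  consensus instances inserted at configured per-peak rates on random
  strands; three sharp synthetic PFMs (97:1 consensus columns) are bundled
  for end-to-end tests.

What the generator does **not** emulate: realistic genome composition and
GC structure, read-level noise, replicate structure for ChIP/PCHi-C,
distance decay of contact frequency, CHiCAGO's statistical model (scores
are drawn, not computed), or correlated motif co-occurrence. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
logic under its stated model, not performance on real sequencing data.

## Problem sizes and determinism

The default study (300 H3K27ac peaks, ~350 interactions per population,
4031 accessibility peaks, 3 motifs) runs the full pipeline in seconds;
`scripts/acceptance.py` re-runs everything, including 1000-vector and
500-pair brute-force oracle comparisons, in well under a minute. All
randomness flows from the single `--seed` argument.

## Known limitations

* The enrichment statistic (Fisher on hit presence vs a residual control)
  is a defined replacement for binned-enrichment tools; it preserves the
  set construction and the FDR < 0.001 gate but can rank borderline motifs
  differently.
* The per-population SE "activity" threshold is the calling cutoff; other
  operationalizations (e.g. a fixed CPM floor) would change borderline
  links.
* `rose_cutoff` fixes the discrete argmax rule; on strongly non-convex
  ranked curves a numeric tangent search could disagree with the discrete
  argmax, though both coincide on convex curves.
* Quantile normalization is defined for the two-sample case only, which is
  all the genotype-change statistic needs.
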