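"""Linking super-enhancers to promoters via promoter-capture interactions.

A super-enhancer (SE) is linked to a gene in a population when three
conditions hold simultaneously in that population:

* at least one high-confidence interaction (score >= 5) joins the gene's
  promoter bait to a restriction fragment overlapping the SE;
* the gene is expressed above 2 RPKM (strict);
* the SE is active, i.e. its summed H3K27ac CPM signal exceeds that
  population's super-enhancer cutoff.

Link strength is the arithmetic mean interaction score over *all* recorded
bait-to-SE-fragment interactions (including sub-threshold ones); the score
threshold gates link existence only.  The module also provides per-row
log2 fold changes relative to the cross-population mean, virtual-4C
viewpoint profiles, and the quantile-normalized percent change of
interaction counts between two genotypes over a target region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from crestreg.cluster import kmeans_rows  # noqa: F401  (shared clustering rule)
from crestreg.intervals import GenomicInterval
from crestreg.io import InteractionRecord
from crestreg.se_calling import SECallResult, StitchedRegion

SCORE_THRESHOLD = 5.0
RPKM_THRESHOLD = 2.0


@dataclass
class SELink:
    """An SE-promoter pair with per-population evidence."""

    se: StitchedRegion
    gene_id: str
    populations: list[str]
    mean_score: dict[str, float]        # NaN when no interaction recorded
    expression_rpkm: dict[str, float]
    se_active: dict[str, bool]
    linked: dict[str, bool]

    @property
    def any_linked(self) -> bool:
        return any(self.linked.values())


def _se_fragment_scores(
    gene_id: str, se: StitchedRegion, interactions: list[InteractionRecord]
) -> list[float]:
    return [
        r.score
        for r in interactions
        if r.bait_gene == gene_id and r.other_end.overlaps(se.interval)
    ]


def mean_interaction_score(
    gene_id: str, se: StitchedRegion, interactions: list[InteractionRecord]
) -> float:
    """Mean score over all recorded bait-to-SE-fragment interactions.

    Returns NaN (a missing-value marker, deliberately not 0) when no
    interaction between the gene's bait and the SE's fragments is recorded.
    """
    scores = _se_fragment_scores(gene_id, se, interactions)
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def link_ses_to_promoters(
    se_results: dict[str, SECallResult],
    interactions: dict[str, list[InteractionRecord]],
    expression_rpkm,
    score_threshold: float = SCORE_THRESHOLD,
    rpkm_threshold: float = RPKM_THRESHOLD,
) -> list[SELink]:
    """Build SELinks for every (SE, gene) pair linked in >=1 population.

    ``expression_rpkm`` is a DataFrame (genes x populations).  Every
    non-empty bait gene appearing in the interaction tables must be present
    in it.
    """
    populations = list(se_results)
    known_genes = set(expression_rpkm.index)
    for pop in populations:
        for r in interactions.get(pop, []):
            if r.bait_gene and r.bait_gene not in known_genes:
                raise ValueError(
                    f"gene {r.bait_gene!r} appears in interactions but not in "
                    "the expression table"
                )

    # candidate catalogue: union of SEs over populations, keyed by interval
    catalogue: dict[str, StitchedRegion] = {}
    for result in se_results.values():
        for region in result.superenhancers:
            catalogue.setdefault(str(region.interval), region)

    # SE activity per population: signal above that population's cutoff
    active: dict[str, dict[str, bool]] = {}
    for pop, result in se_results.items():
        sample_index = result.sample_index
        active[pop] = {
            key: region.signal[sample_index] > result.cutoff_signal
            for key, region in catalogue.items()
        }

    links: list[SELink] = []
    genes = sorted(
        {r.bait_gene for pop in populations for r in interactions.get(pop, []) if r.bait_gene}
    )
    for key in sorted(catalogue):
        se = catalogue[key]
        for gene in genes:
            mean_scores, rpkms, is_active, linked = {}, {}, {}, {}
            for pop in populations:
                recs = interactions.get(pop, [])
                scores = _se_fragment_scores(gene, se, recs)
                mean_scores[pop] = float(np.mean(scores)) if scores else float("nan")
                rpkm = float(expression_rpkm.loc[gene, pop])
                rpkms[pop] = rpkm
                is_active[pop] = bool(active[pop][key])
                linked[pop] = bool(
                    any(s >= score_threshold for s in scores)
                    and rpkm > rpkm_threshold
                    and is_active[pop]
                )
            if any(linked.values()):
                links.append(
                    SELink(
                        se=se,
                        gene_id=gene,
                        populations=populations,
                        mean_score=mean_scores,
                        expression_rpkm=rpkms,
                        se_active=is_active,
                        linked=linked,
                    )
                )
    return links


def relative_log2fc(values, pseudo: float = 0.5) -> np.ndarray:
    """log2((value + pseudo) / (cross-population mean + pseudo)) per entry.

    A row that is constant across populations maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    mean = v.mean()
    return np.log2((v + pseudo) / (mean + pseudo))


# ---------------------------------------------------------------------------
# Virtual 4C


@dataclass
class Virtual4CProfile:
    """A one-viewpoint interaction profile: (fragment, value) track."""

    bait: GenomicInterval
    bait_gene: str
    track: list[tuple[GenomicInterval, float]]

    def total_signal(self) -> float:
        return float(sum(v for _, v in self.track))


def virtual_4c(interactions: list[InteractionRecord], bait_gene: str) -> Virtual4CProfile:
    """Viewpoint profile for one bait gene; duplicate fragments are summed."""
    records = [r for r in interactions if r.bait_gene == bait_gene]
    if not records:
        raise ValueError(f"no interactions recorded for bait gene {bait_gene!r}")
    agg: dict[GenomicInterval, float] = {}
    for r in records:
        frag = GenomicInterval(r.other_end.chrom, r.other_end.start, r.other_end.end)
        agg[frag] = agg.get(frag, 0.0) + r.score
    track = sorted(agg.items(), key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    return Virtual4CProfile(bait=records[0].bait, bait_gene=bait_gene, track=track)


# ---------------------------------------------------------------------------
# Quantile normalization and genotype interaction change


def quantile_normalize_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-normalize two equal-length vectors against each other.

    Each vector's sorted values are replaced by rank-wise means of the two
    sorted vectors; ties within a vector receive the mean of the values
    their positions would get.  After normalization the two sorted vectors
    are identical.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    target = (np.sort(a) + np.sort(b)) / 2.0

    def assign(vec: np.ndarray) -> np.ndarray:
        order = np.argsort(vec, kind="stable")
        out = np.empty_like(target)
        out[order] = target
        # average target values over tied input entries
        for value in np.unique(vec):
            mask = vec == value
            if mask.sum() > 1:
                out[mask] = out[mask].mean()
        return out

    return assign(a), assign(b)


def region_interaction_change(
    interactions_a: list[InteractionRecord],
    interactions_b: list[InteractionRecord],
    bait_gene: str,
    region: GenomicInterval,
) -> float:
    """Percent decrease of a bait's interaction counts over a region, b vs a.

    Raw supporting counts N of the bait's interactions are collected per
    sample over the union of other-end fragments (absent fragments imputed
    as 0), quantile-normalized between the two samples, summed over
    fragments overlapping ``region``, and reported as
    ``100 * (1 - sum_b / sum_a)``.
    """
    counts_a = _bait_counts(interactions_a, bait_gene)
    counts_b = _bait_counts(interactions_b, bait_gene)
    if not counts_a or not counts_b:
        raise ValueError(f"bait gene {bait_gene!r} absent from one of the samples")
    fragments = sorted(
        set(counts_a) | set(counts_b), key=lambda f: (f.chrom, f.start, f.end)
    )
    vec_a = np.array([counts_a.get(f, 0.0) for f in fragments])
    vec_b = np.array([counts_b.get(f, 0.0) for f in fragments])
    norm_a, norm_b = quantile_normalize_pair(vec_a, vec_b)
    in_region = np.array([f.overlaps(region) for f in fragments])
    sum_a = float(norm_a[in_region].sum())
    sum_b = float(norm_b[in_region].sum())
    if sum_a == 0:
        raise ValueError("no normalized signal over the region in sample a")
    return 100.0 * (1.0 - sum_b / sum_a)


def _bait_counts(
    interactions: list[InteractionRecord], bait_gene: str
) -> dict[GenomicInterval, float]:
    counts: dict[GenomicInterval, float] = {}
    for r in interactions:
        if r.bait_gene == bait_gene:
            frag = GenomicInterval(r.other_end.chrom, r.other_end.start, r.other_end.end)
            counts[frag] = counts.get(frag, 0.0) + r.n_reads
    return counts
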