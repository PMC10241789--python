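"""Synthetic pipeline inputs with planted ground truth.

Every downstream stage of the pipeline (super-enhancer calling, interaction
linking, accessibility clustering, motif discovery) can be exercised on data
produced here, with the planted entities recorded so recovery can be scored.

What the generator emulates
---------------------------
* a small multi-chromosome genome with one randomly placed TSS per gene and
  a restriction-fragment map tiling each chromosome (HindIII-like mean
  fragment size of 4 kb);
* heavy-tailed H3K27ac peak counts: a log-normal body (mu=3, sigma=0.8 on
  the raw-count scale) plus planted clusters of >=3 peaks within stitching
  distance whose counts are multiplied by ``se_signal_scale`` in one
  designated population, producing the convex ranked curve with an elbow on
  which the super-enhancer cutoff is defined;
* promoter-capture interactions: an exponential(mean 1) score null, so a
  score of 5 is a meaningful significance boundary (null tail e^-5), with
  planted bait-to-SE links scored 5 + exponential(mean 3) in the designated
  population and strictly below 5 elsewhere; supporting read counts are
  Poisson with a rate increasing in the score;
* expression tables in which planted-link genes are expressed (>2 RPKM)
  only in their designated population;
* a two-condition accessibility matrix with three planted temporal
  profiles (up at condition 2, up at condition 1, flat) plus unstructured
  background rows;
* peak sequences with motif consensus instances inserted at controlled
  per-peak rates.

Determinism: a single integer seed feeds one root stream; each generator
derives its own child stream from a fixed spawn key, so adding a generator
never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crestreg.intervals import GeneAnnotation, GenomicInterval
from crestreg.io import InteractionRecord
from crestreg.motifs import BASES, MotifPFM
from crestreg.se_calling import Peak

_STREAMS = {
    "annotation": 0,
    "h3k27ac": 1,
    "interactions": 2,
    "expression": 3,
    "accessibility": 4,
    "sequences": 5,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults emulate four CNCC subpopulations (FNP, Mx, Md, PA2), a
    HindIII-like fragment map, a strong planted super-enhancer tail
    (x20 signal) and two accessibility conditions with two replicates.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    n_genes: int = 60
    populations: tuple[str, ...] = ("FNP", "Mx", "Md", "PA2")
    n_peaks: int = 300
    n_planted_ses: int = 12
    se_signal_scale: float = 20.0
    n_planted_links: int = 8
    n_background_interactions: int = 300
    fragment_mean_bp: int = 4000
    # accessibility
    conditions: tuple[str, ...] = ("E10.5", "E12.5")
    n_replicates: int = 2
    n_access_peaks: int = 4000
    n_region_peaks: int = 31
    profile_delta_log2: float = 1.5
    access_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length_bp", "n_genes", "n_peaks",
            "n_planted_ses", "n_planted_links", "fragment_mean_bp",
            "n_replicates", "n_access_peaks", "n_region_peaks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.se_signal_scale < 1:
            raise ValueError("se_signal_scale must be >= 1")
        if 3 * self.n_planted_ses > self.n_peaks:
            raise ValueError("n_planted_ses x 3 exceeds n_peaks")

    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def access_samples(self) -> list[str]:
        return [
            f"{cond}_rep{r + 1}" for cond in self.conditions for r in range(self.n_replicates)
        ]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class GroundTruth:
    """Planted entities, recorded for recovery scoring."""

    planted_se_regions: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    planted_se_peaks: list[list[int]] = field(default_factory=list)
    planted_links: list[tuple[int, str, str]] = field(default_factory=list)
    profile_labels: np.ndarray | None = None      # per accessibility peak; 3=background
    region_peak_indices: list[int] = field(default_factory=list)
    motif_truth: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Annotation and fragment map


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], list[GenomicInterval]]:
    """Genes with non-overlapping TSSs plus a gap-free fragment tiling."""
    rng = config.rng("annotation")
    chroms = config.chromosomes()
    margin = 100_000
    spacing = 20_000
    genes: list[GeneAnnotation] = []
    per_chrom = np.array_split(np.arange(config.n_genes), len(chroms))
    for chrom, idx in zip(chroms, per_chrom):
        slots = np.arange(margin, config.chrom_length_bp - margin, spacing)
        if len(slots) < len(idx):
            raise ValueError(
                f"{chrom} is too short ({config.chrom_length_bp} bp) for "
                f"{len(idx)} genes at {spacing} bp spacing"
            )
        positions = np.sort(rng.choice(slots, size=len(idx), replace=False))
        for gi, pos in zip(idx, positions):
            strand = "+" if rng.random() < 0.5 else "-"
            tss = GenomicInterval(chrom, int(pos), int(pos) + 1, strand)
            length = int(rng.integers(1_000, 50_000))
            genes.append(GeneAnnotation(f"gene{gi:04d}", tss, length))

    fragments: list[GenomicInterval] = []
    for chrom in chroms:
        pos = 0
        while pos < config.chrom_length_bp:
            length = max(500, int(rng.exponential(config.fragment_mean_bp)))
            end = min(pos + length, config.chrom_length_bp)
            fragments.append(GenomicInterval(chrom, pos, end))
            pos = end
    return genes, fragments


# ---------------------------------------------------------------------------
# H3K27ac peaks with a planted super-enhancer tail


def simulate_h3k27ac(
    config: SimulationConfig, annotation: list[GeneAnnotation]
) -> tuple[list[Peak], pd.Series, GroundTruth]:
    """Peak intervals with per-population raw counts and planted SE clusters.

    Planted clusters hold 3-5 peaks within stitching distance whose counts
    are multiplied by ``se_signal_scale`` in one designated population;
    cluster peaks avoid promoter windows so they survive filtering.
    """
    rng = config.rng("h3k27ac")
    chroms = config.chromosomes()
    populations = list(config.populations)
    truth = GroundTruth()

    promoter_zones: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for gene in annotation:
        promoter_zones[gene.chrom].append((gene.tss_pos - 3_000, gene.tss_pos + 3_000))

    occupied: dict[str, list[tuple[int, int]]] = {c: list(promoter_zones[c]) for c in chroms}

    def is_free(chrom: str, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in occupied[chrom])

    peaks: list[Peak] = []
    planted_peak_indices: list[list[int]] = []
    n_cluster_peaks = [3 + i % 3 for i in range(config.n_planted_ses)]

    # planted clusters, round-robin over chromosomes and populations
    for i in range(config.n_planted_ses):
        chrom = chroms[i % len(chroms)]
        pop = populations[i % len(populations)]
        k = n_cluster_peaks[i]
        placed = None
        for _ in range(1000):
            anchor = int(rng.integers(200_000, config.chrom_length_bp - 200_000))
            widths = rng.integers(400, 1200, size=k)
            gaps = rng.integers(500, 8_000, size=k - 1) if k > 1 else np.array([], int)
            starts = [anchor]
            for j in range(1, k):
                starts.append(starts[-1] + int(widths[j - 1]) + int(gaps[j - 1]))
            span = (anchor - 15_000, starts[-1] + int(widths[-1]) + 15_000)
            if is_free(chrom, *span):
                placed = (starts, widths, span)
                break
        if placed is None:
            raise ValueError("could not place a planted SE cluster; genome too crowded")
        starts, widths, span = placed
        occupied[chrom].append(span)
        indices = []
        for s, w in zip(starts, widths):
            indices.append(len(peaks))
            peaks.append(Peak(GenomicInterval(chrom, int(s), int(s + w))))
        region = GenomicInterval(chrom, int(starts[0]), int(starts[-1] + widths[-1]))
        truth.planted_se_regions.append((region, pop))
        planted_peak_indices.append(indices)
    truth.planted_se_peaks = planted_peak_indices

    # background peaks anywhere outside occupied zones
    n_background = config.n_peaks - len(peaks)
    placed_bg = 0
    attempts = 0
    while placed_bg < n_background:
        attempts += 1
        if attempts > 100 * config.n_peaks:
            raise ValueError("could not place background peaks; genome too crowded")
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(400, 1200))
        start = int(rng.integers(10_000, config.chrom_length_bp - width - 10_000))
        # keep background peaks beyond stitching distance of anything else so
        # planted clusters are the only multi-peak stitched regions and the
        # planted truth stays identifiable
        if not is_free(chrom, start - 13_000, start + width + 13_000):
            continue
        occupied[chrom].append((start - 13_000, start + width + 13_000))
        peaks.append(Peak(GenomicInterval(chrom, start, start + width)))
        placed_bg += 1

    # raw counts: log-normal body, x scale in the designated population
    n_samples = len(populations)
    counts = np.maximum(1, np.round(rng.lognormal(3.0, 0.8, size=(len(peaks), n_samples))))
    for cluster, (region, pop) in zip(planted_peak_indices, truth.planted_se_regions):
        p = populations.index(pop)
        counts[cluster, p] = np.round(counts[cluster, p] * config.se_signal_scale)
    for peak, row in zip(peaks, counts):
        peak.raw_counts = row.astype(int)

    totals = pd.Series(counts.sum(axis=0).astype(int), index=populations)
    return peaks, totals, truth


def score_se_recovery(truth: GroundTruth, catalogue) -> tuple[float, float]:
    """(recall, precision) of a called SE catalogue against the planted
    regions, matched by exact interval identity."""
    planted = {str(region) for region, _ in truth.planted_se_regions}
    called = {str(r.interval) for r in catalogue}
    if not planted:
        raise ValueError("no planted SE regions in the ground truth")
    tp = len(called & planted)
    recall = tp / len(planted)
    precision = tp / len(called) if called else 0.0
    return recall, precision


def peak_count_frame(peaks: list[Peak], samples: list[str]) -> pd.DataFrame:
    """Raw-count DataFrame (peaks x samples) from Peak objects."""
    data = np.vstack([p.raw_counts for p in peaks])
    index = [str(p.interval) for p in peaks]
    return pd.DataFrame(data, index=index, columns=samples)


# ---------------------------------------------------------------------------
# Promoter-capture interactions and expression


def simulate_interactions(
    config: SimulationConfig,
    annotation: list[GeneAnnotation],
    fragments: list[GenomicInterval],
    truth: GroundTruth,
) -> dict[str, list[InteractionRecord]]:
    """Per-population interaction tables with planted bait-to-SE links."""
    rng = config.rng("interactions")
    populations = list(config.populations)
    frag_by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in fragments:
        frag_by_chrom.setdefault(f.chrom, []).append(f)

    def tss_fragment(gene: GeneAnnotation) -> GenomicInterval:
        for f in frag_by_chrom.get(gene.chrom, []):
            if f.start <= gene.tss_pos < f.end:
                return f
        raise ValueError(f"no restriction fragment contains the TSS of {gene.gene_id}")

    def se_fragments(region: GenomicInterval) -> list[GenomicInterval]:
        return [f for f in frag_by_chrom.get(region.chrom, []) if f.overlaps(region)]

    if not truth.planted_se_regions:
        raise ValueError("ground truth holds no planted SE regions")

    # choose link genes: one gene per planted link, cycling over planted SEs
    genes = sorted(annotation, key=lambda g: g.gene_id)
    link_genes = [genes[i] for i in range(config.n_planted_links)]
    truth.planted_links = []
    tables: dict[str, list[InteractionRecord]] = {p: [] for p in populations}

    for i, gene in enumerate(link_genes):
        se_index = i % len(truth.planted_se_regions)
        region, pop = truth.planted_se_regions[se_index]
        truth.planted_links.append((se_index, gene.gene_id, pop))
        bait = tss_fragment(gene)
        targets = se_fragments(region)
        if not targets:
            raise ValueError(f"planted SE {region} overlaps no restriction fragment")
        for frag in targets:
            for p in populations:
                if p == pop:
                    score = 5.0 + rng.exponential(3.0)
                else:
                    score = min(rng.exponential(1.0), 4.9)
                n_reads = int(rng.poisson(2.0 + 3.0 * score))
                tables[p].append(
                    InteractionRecord(bait, gene.gene_id, frag, n_reads, round(score, 4))
                )

    # exponential(mean 1) background over random bait-fragment pairs
    all_frags = fragments
    for p in populations:
        for _ in range(config.n_background_interactions):
            gene = genes[int(rng.integers(len(genes)))]
            bait = tss_fragment(gene)
            frag = all_frags[int(rng.integers(len(all_frags)))]
            if frag == bait:
                continue
            score = rng.exponential(1.0)
            n_reads = int(rng.poisson(2.0 + 3.0 * score))
            tables[p].append(
                InteractionRecord(bait, gene.gene_id, frag, n_reads, round(score, 4))
            )
    return tables


def simulate_expression(
    config: SimulationConfig,
    annotation: list[GeneAnnotation],
    truth: GroundTruth,
) -> pd.DataFrame:
    """RPKM table (genes x populations); planted-link genes are expressed
    (>2 RPKM) only in their designated population."""
    rng = config.rng("expression")
    populations = list(config.populations)
    values = rng.lognormal(-0.5, 1.0, size=(len(annotation), len(populations)))
    df = pd.DataFrame(values, index=[g.gene_id for g in annotation], columns=populations)
    for _, gene_id, pop in truth.planted_links:
        for p in populations:
            df.loc[gene_id, p] = 5.0 + rng.exponential(5.0) if p == pop else 0.5
    return df


# ---------------------------------------------------------------------------
# Accessibility matrix with planted temporal profiles


def simulate_accessibility(
    config: SimulationConfig,
) -> tuple[list[Peak], pd.DataFrame, pd.Series, GroundTruth]:
    """Two-condition accessibility counts with three planted profiles.

    Profile 0 is up in condition 2, profile 1 up in condition 1, profile 2
    flat; label 3 marks unstructured background rows.  The first
    ``n_region_peaks`` peaks lie inside a contiguous focus region
    (chr1:1,000,000-1,400,000) emulating the interval between the two HIRE
    subdomains.
    """
    rng = config.rng("accessibility")
    samples = config.access_samples()
    n_cond = len(config.conditions)
    truth = GroundTruth()

    peaks: list[Peak] = []
    region_start, region_end = 1_000_000, 1_400_000
    pos = region_start + 2_000
    for _ in range(config.n_region_peaks):
        width = int(rng.integers(300, 800))
        if pos + width >= region_end:
            raise ValueError("focus region too small for requested region peaks")
        peaks.append(Peak(GenomicInterval("chr1", pos, pos + width)))
        pos += width + int(rng.integers(2_000, 9_000))

    placed = 0
    while placed < config.n_access_peaks:
        chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
        width = int(rng.integers(300, 800))
        start = int(rng.integers(10_000, config.chrom_length_bp - width - 10_000))
        if chrom == "chr1" and start < region_end + 20_000 and start + width > region_start - 20_000:
            continue  # keep background out of the focus region
        peaks.append(Peak(GenomicInterval(chrom, start, start + width)))
        placed += 1

    n = len(peaks)
    labels = np.empty(n, dtype=int)
    labels[: config.n_region_peaks] = np.arange(config.n_region_peaks) % 3
    labels[config.n_region_peaks:] = rng.choice(
        [0, 1, 2, 3], size=n - config.n_region_peaks, p=[0.2, 0.2, 0.2, 0.4]
    )

    delta = config.profile_delta_log2
    cond_of_sample = np.repeat(np.arange(n_cond), config.n_replicates)
    effects = {
        0: np.where(cond_of_sample == n_cond - 1, delta, -delta),
        1: np.where(cond_of_sample == 0, delta, -delta),
        2: np.zeros(len(samples)),
    }
    base = rng.uniform(4.0, 8.0, size=n)
    log2_signal = np.empty((n, len(samples)))
    for i in range(n):
        if labels[i] == 3:
            eff = rng.uniform(-delta, delta, size=len(samples))
        else:
            eff = effects[int(labels[i])]
        log2_signal[i] = base[i] + eff + rng.normal(0, config.access_noise_sd, len(samples))
    counts = np.maximum(0, np.round(2.0 ** log2_signal)).astype(int)

    frame = pd.DataFrame(counts, index=[str(p.interval) for p in peaks], columns=samples)
    totals = pd.Series(counts.sum(axis=0), index=samples)
    for peak, row in zip(peaks, counts):
        peak.raw_counts = row
    truth.profile_labels = labels
    truth.region_peak_indices = list(range(config.n_region_peaks))
    return peaks, frame, totals, truth


ACCESS_FOCUS_REGION = GenomicInterval("chr1", 1_000_000, 1_400_000)


# ---------------------------------------------------------------------------
# Sequences with planted motif instances


def demo_motifs() -> list[MotifPFM]:
    """Three sharp synthetic PFMs with distinct consensus sequences."""
    out = []
    for motif_id, consensus in (
        ("SYN1", "TGACGTCAT"),
        ("SYN2", "GGGCGGGAC"),
        ("SYN3", "ATTAGCTAA"),
    ):
        counts = np.full((4, len(consensus)), 1.0)
        for j, base in enumerate(consensus):
            counts[BASES.index(base), j] = 97.0
        out.append(MotifPFM(motif_id, counts, name=motif_id))
    return out


def simulate_sequences(
    config: SimulationConfig,
    peaks: list[Peak],
    motif_set: list[MotifPFM],
    rates: dict[str, float],
    eligible: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Uniform-background sequences with consensus instances planted.

    ``rates[motif_id]`` is the per-peak probability of inserting one
    consensus instance; ``eligible`` optionally restricts, per motif, which
    peaks may receive one (boolean mask over peaks).  Planted positions and
    strands are recorded in the returned ground truth.
    """
    rng = config.rng("sequences")
    truth = GroundTruth()
    sequences: dict[str, str] = {}
    comp = str.maketrans("ACGT", "TGCA")
    for i, peak in enumerate(peaks):
        width = peak.interval.width
        seq = "".join(rng.choice(list(BASES), size=width))
        name = f"peak{i:05d}|{peak.interval}"
        planted: list[tuple[str, int, str]] = []
        for motif in motif_set:
            rate = rates.get(motif.motif_id, 0.0)
            if eligible is not None:
                mask = eligible.get(motif.motif_id)
                if mask is not None and not mask[i]:
                    continue
            if rate <= 0 or rng.random() >= rate:
                continue
            consensus = motif.consensus()
            if width < len(consensus):
                continue
            offset = int(rng.integers(0, width - len(consensus) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else consensus.translate(comp)[::-1]
            seq = seq[:offset] + insert + seq[offset + len(insert):]
            planted.append((motif.motif_id, offset, strand))
        sequences[name] = seq
        if planted:
            truth.motif_truth[name] = planted
    return sequences, truth
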