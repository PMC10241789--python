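"""ROSE-style super-enhancer calling from H3K27ac peaks.

The workflow follows the widely used ROSE recipe with a few fixed choices:

1. drop peaks overlapping promoter windows (+/-2500 bp of a TSS), blacklist
   regions, or chromosomes outside the allowed set;
2. normalize per-sample raw peak counts to counts per million (CPM);
3. stitch peaks whose gap is at most 12.5 kb into candidate regions and sum
   constituent CPMs per sample; stitched regions that come to overlap a
   promoter window are dropped;
4. rank regions by summed signal per sample and place the super-enhancer
   cutoff at the "hockey-stick" elbow: after scaling ranks and signals to
   [0, 1], the cutoff rank maximizes (scaled rank - scaled signal), which is
   where a slope-1 line is tangent to a convex ranked curve;
5. a region is a super-enhancer in a sample if its signal is strictly above
   the cutoff and it contains at least 3 constituent peaks.  The union over
   samples is the putative super-enhancer catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crestreg.intervals import (
    GeneAnnotation,
    GenomicInterval,
    IntervalIndex,
)

PROMOTER_WINDOW_BP = 2500
DEFAULT_STITCH_GAP_BP = 12500
DEFAULT_MIN_PEAKS = 3


@dataclass
class Peak:
    """A peak interval with per-sample raw counts and derived CPM."""

    interval: GenomicInterval
    raw_counts: np.ndarray | None = None   # per sample
    cpm: np.ndarray | None = None          # per sample
    name: str = ""


@dataclass
class StitchedRegion:
    """A merged cluster of peaks; candidate super-enhancer."""

    interval: GenomicInterval
    constituent_peaks: list[Peak]
    signal: np.ndarray  # per-sample summed CPM

    @property
    def n_peaks(self) -> int:
        return len(self.constituent_peaks)


@dataclass
class SECallResult:
    """Per-sample super-enhancer call."""

    sample_id: str
    cutoff_signal: float
    cutoff_rank: int
    superenhancers: list[StitchedRegion]
    ranked_regions: pd.DataFrame = field(repr=False)
    regions: list[StitchedRegion] = field(default_factory=list, repr=False)
    sample_index: int = 0


def promoter_windows(annotation: list[GeneAnnotation],
                     window_bp: int = PROMOTER_WINDOW_BP) -> list[GenomicInterval]:
    """[TSS - window, TSS + window) promoter exclusion windows."""
    out = []
    for gene in annotation:
        start = max(0, gene.tss_pos - window_bp)
        out.append(GenomicInterval(gene.chrom, start, gene.tss_pos + window_bp))
    return out


def compute_cpm(raw_counts: pd.DataFrame, library_totals: pd.Series) -> pd.DataFrame:
    """counts-per-million: raw / library total * 1e6, per sample column."""
    totals = library_totals.reindex(raw_counts.columns)
    if totals.isna().any():
        missing = list(raw_counts.columns[totals.isna()])
        raise ValueError(f"missing library totals for samples {missing}")
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return raw_counts / totals.values * 1e6


def filter_peaks(
    peaks: list[Peak],
    annotation: list[GeneAnnotation],
    blacklist: list[GenomicInterval],
    allowed_chroms: set[str],
    window_bp: int = PROMOTER_WINDOW_BP,
) -> list[Peak]:
    """Drop promoter-overlapping, blacklisted and off-chromosome peaks."""
    if not allowed_chroms:
        raise ValueError("allowed_chroms must be non-empty")
    exclusion = IntervalIndex(promoter_windows(annotation, window_bp) + list(blacklist))
    kept = []
    for peak in peaks:
        if peak.interval.chrom not in allowed_chroms:
            continue
        if exclusion.any_overlap(peak.interval):
            continue
        kept.append(peak)
    return kept


def stitch_peaks(
    peaks: list[Peak],
    gap_bp: int = DEFAULT_STITCH_GAP_BP,
    annotation: list[GeneAnnotation] | None = None,
    window_bp: int = PROMOTER_WINDOW_BP,
) -> list[StitchedRegion]:
    """Merge peaks whose inter-peak gap is <= gap_bp into candidate regions.

    Signals are summed per sample over constituents.  If an annotation is
    given, stitched regions overlapping a promoter window are removed (a
    stitched span can reach into a promoter even when no constituent does).
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    regions: list[StitchedRegion] = []
    current: list[Peak] = []

    def flush() -> None:
        if not current:
            return
        chrom = current[0].interval.chrom
        start = min(p.interval.start for p in current)
        end = max(p.interval.end for p in current)
        signal = np.sum([p.cpm for p in current], axis=0) if current[0].cpm is not None else np.array([])
        regions.append(
            StitchedRegion(GenomicInterval(chrom, start, end), list(current), signal)
        )

    current_end = None
    for peak in ordered:
        if (
            current
            and peak.interval.chrom == current[0].interval.chrom
            and peak.interval.start - current_end <= gap_bp
        ):
            current.append(peak)
            current_end = max(current_end, peak.interval.end)
        else:
            flush()
            current = [peak]
            current_end = peak.interval.end
    flush()

    if annotation is not None:
        exclusion = IntervalIndex(promoter_windows(annotation, window_bp))
        regions = [r for r in regions if not exclusion.any_overlap(r.interval)]
    return regions


def rose_cutoff(signals) -> tuple[float, int]:
    """Hockey-stick cutoff on a ranked signal vector.

    Sort ascending as s_1..s_n and scale ranks u_i = i/n and signals
    v_i = (s_i - s_1) / (s_n - s_1).  The cutoff rank is the (1-based,
    smallest on ties) argmax of u_i - v_i; the cutoff value is the signal at
    that rank.  Super-enhancers are regions with signal strictly above the
    cutoff value.  If all signals are equal the cutoff is that value and
    nothing is above it.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 signals")
    if s[-1] == s[0]:
        return float(s[0]), n
    u = np.arange(1, n + 1) / n
    v = (s - s[0]) / (s[-1] - s[0])
    diff = u - v
    rank = int(np.flatnonzero(diff == diff.max())[0]) + 1  # smallest index on ties
    return float(s[rank - 1]), rank


def call_superenhancers(
    regions: list[StitchedRegion],
    sample_index: int,
    sample_id: str,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> SECallResult:
    """Call super-enhancers for one sample.

    The cutoff is computed on all stitched-region signals (before the
    constituent-count filter); super-enhancers must then be strictly above
    the cutoff *and* contain at least ``min_peaks`` peaks.
    """
    if min_peaks < 1:
        raise ValueError("min_peaks must be >= 1")
    signals = np.array([r.signal[sample_index] for r in regions], dtype=float)
    cutoff_value, cutoff_rank = rose_cutoff(signals)
    order = np.argsort(-signals, kind="stable")
    rows = []
    ses = []
    rank_of = {int(i): r + 1 for r, i in enumerate(order)}
    for i, region in enumerate(regions):
        is_se = signals[i] > cutoff_value and region.n_peaks >= min_peaks
        rows.append(
            {
                "region": str(region.interval),
                "rank": rank_of[i],
                "signal": signals[i],
                "n_peaks": region.n_peaks,
                "is_se": is_se,
            }
        )
        if is_se:
            ses.append(region)
    ranked = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    return SECallResult(
        sample_id=sample_id,
        cutoff_signal=cutoff_value,
        cutoff_rank=cutoff_rank,
        superenhancers=ses,
        ranked_regions=ranked,
        regions=list(regions),
        sample_index=sample_index,
    )


def se_catalogue(results: list[SECallResult]) -> list[StitchedRegion]:
    """Union of super-enhancers over samples (regions active in >=1 sample)."""
    seen: dict[str, StitchedRegion] = {}
    for result in results:
        for region in result.superenhancers:
            seen.setdefault(str(region.interval), region)
    return sorted(
        seen.values(), key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
    )
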