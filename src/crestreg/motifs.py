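"""Accessibility-profile-driven transcription-factor motif discovery.

The workflow mirrors a common design in developmental epigenomics: ATAC-seq
peaks are split into promoter and enhancer peaks; enhancer accessibility is
expressed as log2(CPM + 1) relative to the per-peak mean across samples; the
peaks inside a focus region are clustered into temporal profiles; all
enhancers are ranked by Pearson correlation to each profile; the top-ranked,
non-overlapping peak sets are tested for motif enrichment against the
residual control set (one-sided Fisher exact, Benjamini-Hochberg FDR); and
the enriched motifs are reduced to representatives by hit-rate and
similarity clustering.

PWM scanning uses absolute log2-odds scores against a uniform background
(pseudocount 0.01 per PFM cell), both strands, threshold 10.0 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from crestreg.cluster import kmeans_rows
from crestreg.intervals import GeneAnnotation, GenomicInterval, TssIndex

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class MotifPFM:
    """A position frequency matrix: 4 rows (A, C, G, T) x L columns."""

    motif_id: str
    counts: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every column must have positive sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self, pseudocount: float = 0.01) -> np.ndarray:
        """Column-normalized probabilities with a per-cell pseudocount."""
        m = self.counts + pseudocount
        return m / m.sum(axis=0, keepdims=True)

    def log_odds(self, pseudocount: float = 0.01, background: float = 0.25) -> np.ndarray:
        """log2-odds score matrix against a uniform background."""
        return np.log2(self.probabilities(pseudocount) / background)

    def reverse_complement(self) -> "MotifPFM":
        return MotifPFM(self.motif_id, self.counts[::-1, ::-1].copy(), self.name)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class MotifHit:
    peak_index: int
    offset: int       # 0-based start of the hit window on the forward strand
    strand: str       # "+" or "-"
    score: float


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes; anything not ACGT becomes 4 (N)."""
    seq = sequence.upper()
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return codes


def scan_pwm(
    sequence: str,
    motif: MotifPFM,
    tau: float = 10.0,
    pseudocount: float = 0.01,
    peak_index: int = 0,
) -> list[MotifHit]:
    """Scan one sequence with a PWM on both strands.

    Windows containing N (or any non-ACGT base) score -inf and never
    pass the threshold.  A sequence shorter than the motif yields no hits.
    """
    L = motif.length
    codes = _encode(sequence)
    n = len(codes) - L + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~np.any(windows == 4, axis=1)
    hits: list[MotifHit] = []
    for strand, pwm in (("+", motif), ("-", motif.reverse_complement())):
        lods = pwm.log_odds(pseudocount)
        safe = np.where(windows == 4, 0, windows)
        scores = lods[safe, np.arange(L)].sum(axis=1)
        scores[~valid] = -np.inf
        for off in np.nonzero(scores >= tau)[0]:
            hits.append(MotifHit(peak_index, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def count_hits(
    sequences: list[str], motif: MotifPFM, tau: float = 10.0, pseudocount: float = 0.01
) -> np.ndarray:
    """Number of hits per sequence."""
    return np.array(
        [len(scan_pwm(s, motif, tau, pseudocount, i)) for i, s in enumerate(sequences)]
    )


def hit_rate_per_kb(hits_per_peak: np.ndarray, peak_widths_bp: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-peak hit rate (hits x 1000 / width) and its unweighted mean."""
    hits_per_peak = np.asarray(hits_per_peak, dtype=float)
    widths = np.asarray(peak_widths_bp, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("peak widths must be positive")
    rates = hits_per_peak * 1000.0 / widths
    return rates, float(rates.mean())


# ---------------------------------------------------------------------------
# Enhancer classification and accessibility matrices


def classify_enhancer_peaks(
    peaks: list[GenomicInterval],
    annotation: list[GeneAnnotation],
    tss_dist_bp: int = 1000,
    sex_chroms: tuple[str, ...] = ("chrX", "chrY"),
) -> tuple[list[int], list[int]]:
    """Split peaks into enhancer and promoter indices.

    A peak is a promoter peak iff the distance from its midpoint to the
    nearest TSS is strictly smaller than ``tss_dist_bp``.  Peaks on sex
    chromosomes are dropped from the enhancer set (mixed-sex samples make
    sex-chromosome coverage uninterpretable).
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    tss_index = TssIndex(annotation)
    enhancers: list[int] = []
    promoters: list[int] = []
    for i, peak in enumerate(peaks):
        d = tss_index.nearest_distance(peak.chrom, peak.midpoint)
        if d is not None and d < tss_dist_bp:
            promoters.append(i)
        elif peak.chrom not in sex_chroms:
            enhancers.append(i)
    return enhancers, promoters


@dataclass
class AccessibilityMatrix:
    """log2(CPM+1) accessibility and its per-peak mean-centered form."""

    peaks: list[GenomicInterval]
    logcpm: pd.DataFrame     # peaks x samples
    relative: pd.DataFrame   # logcpm minus per-row mean

    @property
    def samples(self) -> list[str]:
        return list(self.logcpm.columns)


def build_accessibility_matrix(
    peaks: list[GenomicInterval],
    counts: pd.DataFrame,
    library_totals: pd.Series,
) -> AccessibilityMatrix:
    """CPM-normalize, log2(x+1)-transform and row-center raw peak counts."""
    totals = library_totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("library totals must be positive for every sample")
    if len(peaks) != len(counts):
        raise ValueError("peaks and count rows must align")
    cpm = counts / totals.values * 1e6
    logcpm = np.log2(cpm + 1.0)
    relative = logcpm.sub(logcpm.mean(axis=1), axis=0)
    return AccessibilityMatrix(peaks=list(peaks), logcpm=logcpm, relative=relative)


@dataclass
class ProfileClusters:
    """Accessibility-profile clusters of the focus-region peaks."""

    region_peak_indices: list[int]
    labels: np.ndarray            # cluster label per region peak, 0..k-1
    mean_profiles: np.ndarray     # k x n_samples mean relative accessibility
    samples: list[str]


def cluster_region_peaks(
    matrix: AccessibilityMatrix,
    region: GenomicInterval,
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
) -> ProfileClusters:
    """K-means the relative accessibility of peaks inside a focus region."""
    idx = [i for i, p in enumerate(matrix.peaks) if p.overlaps(region)]
    if len(idx) < k:
        raise ValueError(
            f"region holds {len(idx)} peaks but k={k} clusters were requested"
        )
    rows = matrix.relative.values[idx]
    labels = kmeans_rows(rows, k=k, seed=seed, restarts=restarts)
    means = np.vstack([rows[labels == c].mean(axis=0) for c in range(k)])
    if np.any(~np.isfinite(means)):
        raise ValueError("degenerate clustering: an empty cluster was produced")
    return ProfileClusters(
        region_peak_indices=idx,
        labels=labels,
        mean_profiles=means,
        samples=matrix.samples,
    )


# ---------------------------------------------------------------------------
# Correlation ranking and peak-set construction


@dataclass
class PeakSets:
    """Top-correlated peak sets (pairwise disjoint) plus the residual control."""

    sets: list[list[int]]     # one list of peak indices per profile
    control: list[int]
    correlations: np.ndarray  # n_peaks x k Pearson r
    assignment: np.ndarray    # argmax profile per peak


def _pearson_rows_vs_profiles(rows: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson r of each row against each profile; zero-variance rows get 0."""
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    prof_c = profiles - profiles.mean(axis=1, keepdims=True)
    row_sd = np.sqrt((rows_c**2).sum(axis=1))
    prof_sd = np.sqrt((prof_c**2).sum(axis=1))
    if np.any(prof_sd == 0):
        raise ValueError("profiles must be non-constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rows_c @ prof_c.T) / np.outer(row_sd, prof_sd)
    r[row_sd == 0, :] = 0.0
    return r


def rank_by_profile(
    matrix: AccessibilityMatrix,
    enhancer_indices: list[int],
    profiles: np.ndarray,
    top_n: int = 1000,
) -> PeakSets:
    """Assign each enhancer to its best-correlated profile, keep the top_n.

    Disjointness is enforced by assigning each peak to its argmax profile
    (ties to the lowest profile index) before ranking; within a profile,
    peaks are ranked by r descending with genomic coordinate order breaking
    ties.  Residual peaks form the control set.
    """
    rows = matrix.relative.values[enhancer_indices]
    r = _pearson_rows_vs_profiles(rows, profiles)
    assignment = r.argmax(axis=1)  # argmax takes the first (lowest) on ties
    k = profiles.shape[0]
    sets: list[list[int]] = []
    chosen: set[int] = set()
    order_key = {
        j: (matrix.peaks[enhancer_indices[j]].chrom,
            matrix.peaks[enhancer_indices[j]].start,
            matrix.peaks[enhancer_indices[j]].end)
        for j in range(len(enhancer_indices))
    }
    for c in range(k):
        members = [j for j in range(len(enhancer_indices)) if assignment[j] == c]
        members.sort(key=lambda j: (-r[j, c],) + order_key[j])
        top = members[:top_n]
        sets.append([enhancer_indices[j] for j in top])
        chosen.update(top)
    control = [enhancer_indices[j] for j in range(len(enhancer_indices)) if j not in chosen]
    return PeakSets(sets=sets, control=control, correlations=r, assignment=assignment)


# ---------------------------------------------------------------------------
# Motif enrichment


def motif_enrichment(
    peak_sets: PeakSets,
    hits_per_peak: dict[str, np.ndarray],
    fdr_threshold: float = 0.001,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of motif presence, set vs control.

    For each (motif, set) the 2x2 table counts peaks with >=1 hit vs
    without, in the set vs the residual control.  P-values are one-sided in
    the enrichment direction and BH-corrected across all (motif, set) pairs.
    A motif is selected if its FDR is below ``fdr_threshold`` in any set.
    """
    if not peak_sets.control:
        raise ValueError("control set is empty; enrichment is undefined")
    records = []
    control = np.array(peak_sets.control)
    for motif_id, hits in hits_per_peak.items():
        has_hit = np.asarray(hits) > 0
        c_with = int(has_hit[control].sum())
        c_without = len(control) - c_with
        for set_idx, members in enumerate(peak_sets.sets):
            m = np.array(members, dtype=int)
            s_with = int(has_hit[m].sum()) if len(m) else 0
            s_without = len(m) - s_with
            table = [[s_with, s_without], [c_with, c_without]]
            _, p = stats.fisher_exact(table, alternative="greater")
            odds = np.nan
            if s_without > 0 and c_with > 0:
                odds = (s_with * c_without) / (s_without * c_with)
            records.append(
                {
                    "motif_id": motif_id,
                    "set": set_idx + 1,
                    "set_with_hit": s_with,
                    "set_size": len(m),
                    "control_with_hit": c_with,
                    "control_size": len(control),
                    "odds_ratio": odds,
                    "p_value": p,
                }
            )
    table = pd.DataFrame.from_records(records)
    _, fdr, _, _ = multipletests(table["p_value"].values, method="fdr_bh")
    table["fdr"] = fdr
    selected_ids = set(table.loc[table["fdr"] < fdr_threshold, "motif_id"])
    table["selected"] = table["motif_id"].isin(selected_ids)
    return table


# ---------------------------------------------------------------------------
# Motif similarity and representative selection


def motif_similarity(a: MotifPFM, b: MotifPFM, min_overlap: int = 4,
                     pseudocount: float = 0.01) -> float:
    """Maximum Pearson correlation over ungapped alignments of two motifs.

    All relative offsets with at least ``min_overlap`` overlapping columns
    are scored (shorter motifs use their full length), in both the forward
    and the reverse-complement orientation of ``b``; columns are compared as
    flattened probability submatrices.
    """
    pa = a.probabilities(pseudocount)
    best = -1.0
    for variant in (b, b.reverse_complement()):
        pb = variant.probabilities(pseudocount)
        la, lb = pa.shape[1], pb.shape[1]
        need = min(min_overlap, la, lb)
        for shift in range(-(lb - need), la - need + 1):
            a_lo, a_hi = max(0, shift), min(la, shift + lb)
            b_lo = a_lo - shift
            b_hi = b_lo + (a_hi - a_lo)
            x = pa[:, a_lo:a_hi].ravel()
            y = pb[:, b_lo:b_hi].ravel()
            if x.std() == 0 or y.std() == 0:
                r = 1.0 if np.allclose(x, y) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            best = max(best, r)
    return best


def similarity_matrix(motifs: list[MotifPFM], min_overlap: int = 4) -> np.ndarray:
    n = len(motifs)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = motif_similarity(motifs[i], motifs[j], min_overlap)
    return S


@dataclass
class RepresentativeSelection:
    kept_ids: list[str]             # motifs in the higher-hit-rate k=2 cluster
    similarity: np.ndarray          # S over kept motifs
    cluster_labels: np.ndarray      # k-means labels on distance rows
    representatives: dict[int, str]  # cluster -> representative motif_id


def select_representatives(
    motifs: list[MotifPFM],
    mean_rates: dict[str, float],
    seed: int = 0,
    n_similarity_clusters: int = 10,
    restarts: int = 10,
) -> RepresentativeSelection:
    """Reduce an enriched-motif list to per-cluster representatives.

    Steps: (1) 1-D k-means (k=2) on mean hit rates; keep the higher-mean
    cluster; (2) pairwise similarity S, distance D = 1 - S; (3) k-means
    (k = min(10, n)) on the rows of D; (4) per cluster the representative is
    the motif with the least average distance to the other members, ties
    broken by lexicographic motif id.
    """
    if len(motifs) < 2:
        raise ValueError("need at least 2 motifs")
    ids = [m.motif_id for m in motifs]
    rates = np.array([[mean_rates[i]] for i in ids])
    rate_labels = kmeans_rows(rates, k=2, seed=seed, restarts=restarts)
    means = [
        rates[rate_labels == c].mean() if np.any(rate_labels == c) else -np.inf
        for c in (0, 1)
    ]
    keep_label = int(np.argmax(means))
    kept = [m for m, lab in zip(motifs, rate_labels) if lab == keep_label]
    if len(kept) < 2:
        raise ValueError("fewer than 2 motifs in the high-hit-rate cluster")
    S = similarity_matrix(kept)
    D = 1.0 - S
    k = min(n_similarity_clusters, len(kept))
    labels = kmeans_rows(D, k=k, seed=seed, restarts=restarts)
    representatives: dict[int, str] = {}
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        if len(members) == 0:
            continue
        best: tuple[float, str] | None = None
        for i in members:
            others = members[members != i]
            avg = float(D[i, others].mean()) if len(others) else 0.0
            key = (avg, kept[i].motif_id)
            if best is None or key < best:
                best = key
        representatives[c] = best[1]
    return RepresentativeSelection(
        kept_ids=[m.motif_id for m in kept],
        similarity=S,
        cluster_labels=labels,
        representatives=representatives,
    )
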