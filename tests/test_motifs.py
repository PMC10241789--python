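"""Motif workflow: classification, accessibility matrices, correlation
ranking, PWM scanning, enrichment and representative selection."""

import numpy as np
import pandas as pd
import pytest

from crestreg import motifs as mf
from crestreg.intervals import GeneAnnotation, GenomicInterval
from oracles import brute_force_pwm_hits, pearson_direct


def gene(chrom, tss):
    return GeneAnnotation(f"g_{chrom}_{tss}", GenomicInterval(chrom, tss, tss + 1), 1000)


def sharp_motif(consensus, motif_id="M1"):
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts[mf.BASES.index(base), j] = 97.0
    return mf.MotifPFM(motif_id, counts)


# ---------------------------------------------------------------------------
# classification


def test_promoter_classification_boundaries():
    annotation = [gene("chr1", 10_000)]
    near = GenomicInterval("chr1", 8_801, 9_201)   # midpoint 9001, 999 bp away
    exact = GenomicInterval("chr1", 8_800, 9_200)  # midpoint 9000, exactly 1000
    enh, prom = mf.classify_enhancer_peaks([near, exact], annotation)
    assert prom == [0]
    assert enh == [1]


def test_sex_chromosome_peaks_dropped_from_enhancers():
    annotation = [gene("chr1", 10_000)]
    peaks = [GenomicInterval("chrX", 500_000, 501_000), GenomicInterval("chr2", 500_000, 501_000)]
    enh, prom = mf.classify_enhancer_peaks(peaks, annotation)
    assert enh == [1] and prom == []


def test_classify_requires_annotation():
    with pytest.raises(ValueError):
        mf.classify_enhancer_peaks([GenomicInterval("chr1", 0, 100)], [])


# ---------------------------------------------------------------------------
# accessibility matrix


def test_accessibility_matrix_values_and_centering():
    peaks = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)]
    counts = pd.DataFrame({"s1": [0, 1], "s2": [1, 3]}, index=["p0", "p1"])
    totals = pd.Series({"s1": 1_000_000, "s2": 1_000_000})
    matrix = mf.build_accessibility_matrix(peaks, counts, totals)
    assert matrix.logcpm.loc["p0", "s1"] == 0.0      # log2(0 + 1)
    assert matrix.logcpm.loc["p0", "s2"] == 1.0      # CPM 1 -> log2(2)
    np.testing.assert_allclose(matrix.relative.sum(axis=1), 0.0, atol=1e-12)


def test_accessibility_matrix_rejects_bad_totals():
    peaks = [GenomicInterval("chr1", 0, 100)]
    counts = pd.DataFrame({"s1": [5]})
    with pytest.raises(ValueError):
        mf.build_accessibility_matrix(peaks, counts, pd.Series({"s1": 0}))


# ---------------------------------------------------------------------------
# profile clustering and ranking


def test_cluster_region_peaks_requires_enough_peaks(accessibility):
    peaks, counts, totals, _ = accessibility
    matrix = mf.build_accessibility_matrix([p.interval for p in peaks], counts, totals)
    tiny = GenomicInterval("chr1", 1_000_000, 1_003_000)
    with pytest.raises(ValueError):
        mf.cluster_region_peaks(matrix, tiny, k=3)


def _toy_matrix(rows, samples=("a", "b", "c", "d")):
    peaks = [GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500)
             for i in range(len(rows))]
    logcpm = pd.DataFrame(rows, columns=list(samples),
                          index=[str(p) for p in peaks])
    relative = logcpm.sub(logcpm.mean(axis=1), axis=0)
    return mf.AccessibilityMatrix(peaks, logcpm, relative)


def test_rank_by_profile_perfect_and_anti_correlation():
    profiles = np.array([[1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, -1.0, 1.0]])
    matrix = _toy_matrix([
        [2.0, 0.0, 2.0, 0.0],    # r = +1 with profile 0
        [0.0, 2.0, 0.0, 2.0],    # r = +1 with profile 1 (= -1 with 0)
        [5.0, 5.0, 5.0, 5.0],    # zero variance -> r = 0, ties -> profile 0
    ])
    sets = mf.rank_by_profile(matrix, [0, 1, 2], profiles, top_n=1)
    assert sets.correlations[0, 0] == pytest.approx(1.0)
    assert sets.correlations[1, 0] == pytest.approx(-1.0)
    assert sets.correlations[2, 0] == 0.0
    assert sets.sets[0] == [0] and sets.sets[1] == [1]
    assert sets.control == [2]


def test_rank_by_profile_sets_disjoint_and_bounded(accessibility):
    peaks, counts, totals, _ = accessibility
    matrix = mf.build_accessibility_matrix([p.interval for p in peaks], counts, totals)
    clusters = mf.cluster_region_peaks(
        matrix, GenomicInterval("chr1", 1_000_000, 1_400_000), seed=0
    )
    enh = list(range(len(peaks)))
    sets = mf.rank_by_profile(matrix, enh, clusters.mean_profiles, top_n=1000)
    all_members = [i for s in sets.sets for i in s]
    assert len(all_members) == len(set(all_members))           # pairwise disjoint
    assert all(len(s) <= 1000 for s in sets.sets)
    assert sorted(all_members + sets.control) == sorted(enh)   # partition


def test_rank_correlations_match_direct_pearson(accessibility):
    peaks, counts, totals, _ = accessibility
    matrix = mf.build_accessibility_matrix([p.interval for p in peaks], counts, totals)
    clusters = mf.cluster_region_peaks(
        matrix, GenomicInterval("chr1", 1_000_000, 1_400_000), seed=0
    )
    enh = list(range(40))
    sets = mf.rank_by_profile(matrix, enh, clusters.mean_profiles)
    rows = matrix.relative.values
    for j, i in enumerate(enh[:10]):
        for c in range(3):
            expected = pearson_direct(list(rows[i]), list(clusters.mean_profiles[c]))
            assert sets.correlations[j, c] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# PWM scanning


def test_consensus_scores_match_hand_arithmetic():
    motif = sharp_motif("ACGTAC")
    # per-position probability ~0.97 consensus, ~0.0101 off
    hits = mf.scan_pwm("ACGTAC", motif, tau=10.0)
    assert any(h.strand == "+" and h.offset == 0 for h in hits)
    (fwd,) = [h for h in hits if h.strand == "+"]
    assert fwd.score == pytest.approx(6 * np.log2((97.01 / 100.04) / 0.25), abs=1e-6)
    assert fwd.score == pytest.approx(11.74, abs=0.01)
    # one mismatch drops the score below the threshold (~5.14)
    assert mf.scan_pwm("ACGTAG", motif, tau=10.0) == []


def test_reverse_complement_symmetry():
    motif = sharp_motif("ACGTACGT")
    seq = "TTTACGTACGTTTT"
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    assert len(mf.scan_pwm(seq, motif)) == len(mf.scan_pwm(rc, motif))


def test_short_sequence_and_n_windows():
    motif = sharp_motif("ACGTAC")
    assert mf.scan_pwm("ACGTA", motif) == []          # length L-1
    assert mf.scan_pwm("ACGNAC", motif) == []         # N voids the window


def test_scan_matches_bruteforce_oracle(rng):
    for _ in range(40):
        L = int(rng.integers(4, 13))
        counts = rng.integers(0, 30, size=(4, L)) + 1
        motif = mf.MotifPFM("R", counts.astype(float))
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=int(rng.integers(L, 120))))
        tau = float(rng.uniform(-2, 6))
        got = sorted((h.offset, h.strand) for h in mf.scan_pwm(seq, motif, tau))
        assert got == brute_force_pwm_hits(seq, motif, tau)


# ---------------------------------------------------------------------------
# hit rates and enrichment


def test_hit_rate_per_kb():
    rates, mean = mf.hit_rate_per_kb([2, 0], [500, 1_000])
    np.testing.assert_allclose(rates, [4.0, 0.0])
    assert mean == 2.0


def test_enrichment_null_set_not_selected(rng):
    # both sets drawn from the same hit distribution: nothing should pass
    n = 400
    hits = {"M": (rng.random(2 * n) < 0.2).astype(int)}
    sets = mf.PeakSets(
        sets=[list(range(n))], control=list(range(n, 2 * n)),
        correlations=np.zeros((2 * n, 1)), assignment=np.zeros(2 * n, int),
    )
    table = mf.motif_enrichment(sets, hits, fdr_threshold=0.001)
    assert not table["selected"].any()
    assert (table["p_value"] > 0.01).all()


def test_enrichment_empty_control_is_error():
    sets = mf.PeakSets(sets=[[0]], control=[], correlations=np.zeros((1, 1)),
                       assignment=np.zeros(1, int))
    with pytest.raises(ValueError):
        mf.motif_enrichment(sets, {"M": np.array([1])})


def test_bh_fdr_monotone_in_sorted_p(rng):
    hits = {f"M{i}": (rng.random(300) < rng.uniform(0.05, 0.5)).astype(int)
            for i in range(6)}
    sets = mf.PeakSets(
        sets=[list(range(100)), list(range(100, 200))], control=list(range(200, 300)),
        correlations=np.zeros((300, 2)), assignment=np.zeros(300, int),
    )
    table = mf.motif_enrichment(sets, hits).sort_values("p_value")
    assert table["fdr"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# similarity and representatives


def test_similarity_diagonal_and_symmetry():
    motifs = [sharp_motif("ACGTAC", "A"), sharp_motif("GGGCCC", "B"),
              sharp_motif("ACGTACGT", "C")]
    S = mf.similarity_matrix(motifs)
    np.testing.assert_allclose(np.diag(S), 1.0)
    np.testing.assert_allclose(S, S.T)
    assert np.all(S <= 1.0 + 1e-12) and np.all(S >= -1.0 - 1e-12)


def test_similarity_detects_shifted_and_rc_copies():
    base = sharp_motif("ACGTACGTA", "base")
    shifted = sharp_motif("CGTACGTAC", "shift")   # 1-shift of the same core
    rc = base.reverse_complement()
    rc.motif_id = "rc"
    unrelated = sharp_motif("GGGGGCCCC", "other")
    assert mf.motif_similarity(base, rc) == pytest.approx(1.0, abs=1e-9)
    assert mf.motif_similarity(base, shifted) > 0.95
    assert mf.motif_similarity(base, unrelated) < 0.8


def test_representatives_tie_breaks_lexicographically():
    motifs = [sharp_motif("ACGTAC", i) for i in ("zeta", "alpha", "mid")]
    rates = {"zeta": 5.0, "alpha": 5.0, "mid": 5.0, "low": 0.0}
    motifs.append(sharp_motif("GGGCCC", "low"))
    sel = mf.select_representatives(motifs, rates, seed=0, n_similarity_clusters=1)
    assert sel.kept_ids == ["zeta", "alpha", "mid"]   # higher-rate k=2 cluster
    assert list(sel.representatives.values()) == ["alpha"]


def test_representatives_recover_planted_families():
    fam1 = [sharp_motif(c, f"f1_{i}") for i, c in
            enumerate(["ACGTACGTA", "CGTACGTAC", "GTACGTACG"])]
    fam2 = [sharp_motif(c, f"f2_{i}") for i, c in
            enumerate(["GGGGCCCCT", "GGGCCCCTG", "GGCCCCTGA"])]
    decoys = [sharp_motif("TTTTAAAAT", "d1"), sharp_motif("TTTAAAATT", "d2")]
    motifs = fam1 + fam2 + decoys
    rates = {m.motif_id: 5.0 for m in fam1 + fam2} | {"d1": 0.2, "d2": 0.2}
    sel = mf.select_representatives(motifs, rates, seed=0, n_similarity_clusters=2)
    assert set(sel.kept_ids) == {m.motif_id for m in fam1 + fam2}
    families = {}
    for m, lab in zip(sel.kept_ids, sel.cluster_labels):
        families.setdefault(int(lab), set()).add(m.split("_")[0])
    assert sorted(map(sorted, families.values())) == [["f1"], ["f2"]]
    # representative is the brute-force medoid of its cluster
    D = 1.0 - sel.similarity
    for c, rep in sel.representatives.items():
        members = np.nonzero(sel.cluster_labels == c)[0]
        avg = {
            sel.kept_ids[i]: D[i, members[members != i]].mean() for i in members
        }
        best = min(sorted(avg), key=lambda k: avg[k])
        assert rep == best


def test_select_representatives_needs_two_motifs():
    with pytest.raises(ValueError):
        mf.select_representatives([sharp_motif("ACGTAC")], {"M1": 1.0})
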