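"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected result by direct enumeration or naive
arithmetic, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def brute_force_rose_rank(signals) -> tuple[float, int]:
    """Exhaustive argmax of (i/n - scaled signal) over an ascending sort."""
    s = sorted(float(x) for x in signals)
    n = len(s)
    lo, hi = s[0], s[-1]
    if hi == lo:
        return lo, n
    best_i, best_val = None, None
    for i in range(1, n + 1):
        u = i / n
        v = (s[i - 1] - lo) / (hi - lo)
        if best_val is None or u - v > best_val:
            best_val, best_i = u - v, i
    return s[best_i - 1], best_i


def brute_force_overlap(a, b) -> bool:
    """Base-by-base overlap check on small intervals."""
    if a.chrom != b.chrom:
        return False
    return bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_pwm_hits(sequence: str, motif, tau: float, pseudocount: float = 0.01):
    """Naive per-window, per-position PWM scoring on both strands."""
    probs = motif.probabilities(pseudocount)
    L = motif.length
    seq = sequence.upper()
    hits = []
    for strand in ("+", "-"):
        for off in range(len(seq) - L + 1):
            window = seq[off:off + L]
            if strand == "-":
                window = "".join(_COMP[b] for b in reversed(window))
            score = 0.0
            ok = True
            for j, base in enumerate(window):
                if base not in "ACGT":
                    ok = False
                    break
                score += math.log2(probs["ACGT".index(base), j] / 0.25)
            if ok and score >= tau:
                hits.append((off, strand))
    return sorted(hits)


def hypergeom_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (enrichment) Fisher p for table [[a, b], [c, d]].

    Exact rational arithmetic: sum of hypergeometric point masses for all
    tables at least as extreme (a' >= a) with the same margins.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    total = math.comb(n, col1)
    p = Fraction(0)
    for a2 in range(a, min(row1, col1) + 1):
        c2 = col1 - a2
        if c2 < 0 or c2 > c + d:
            continue
        p += Fraction(math.comb(row1, a2) * math.comb(n - row1, c2), total)
    return p


def pearson_direct(x, y) -> float:
    """Textbook Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den
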