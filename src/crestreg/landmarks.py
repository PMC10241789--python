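"""Genomic landmarks of the Hoxa2 long-range regulatory landscape (mm10).

HIRE1 and HIRE2 (Hoxa Inter-TAD Regulatory Elements) are the two multi-SE
subdomains roughly 1.07 and 1.33 Mb centromeric of the Hoxa2 locus that
contact its promoter across a TAD boundary in second-pharyngeal-arch and
pinna neural crest cells.  Coordinates below are 1-based browser
coordinates on GRCm38/mm10, converted to the package's 0-based half-open
convention on construction.
"""

from crestreg.intervals import GenomicInterval, from_one_based

HIRE1: GenomicInterval = from_one_based("chr6", 50_913_170, 51_087_888)
HIRE2: GenomicInterval = from_one_based("chr6", 50_789_172, 50_828_639)

# The focus interval between HIRE2 and HIRE1 used for accessibility-profile
# clustering of ATAC peaks (31 peaks fall inside it in E10.5 PA2 / E12.5
# pinna data).
HIRE_SPAN: GenomicInterval = from_one_based("chr6", 50_789_172, 51_087_888)


def length_kb(interval: GenomicInterval) -> float:
    """Interval length in kilobases."""
    return interval.width / 1000.0
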