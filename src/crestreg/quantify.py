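"""Expression-level utilities: RPKM and delta-delta-Ct quantification."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


def rpkm(count: int, gene_length_bp: int, library_total: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    return count / (gene_length_bp / 1000.0) / (library_total / 1e6)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene cycle thresholds."""

    sample_id: str
    genotype: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {ct}")


def delta_delta_ct(records: list[QpcrRecord], wildtype_label: str) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    dCt_i = ct_target_i - ct_reference_i; ddCt_i = dCt_i - mean(dCt over
    wild-type samples); relative expression = 2^(-ddCt).  By construction the
    geometric mean of the wild-type relative expressions is exactly 1.
    """
    wt = [r for r in records if r.genotype == wildtype_label]
    if not wt:
        raise ValueError(f"no records with wild-type label {wildtype_label!r}")
    wt_mean_dct = sum(r.ct_target - r.ct_reference for r in wt) / len(wt)
    rows = []
    for r in records:
        dct = r.ct_target - r.ct_reference
        ddct = dct - wt_mean_dct
        rows.append(
            {
                "sample_id": r.sample_id,
                "genotype": r.genotype,
                "delta_ct": dct,
                "delta_delta_ct": ddct,
                "relative_expression": 2.0 ** (-ddct),
            }
        )
    return pd.DataFrame(rows)
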