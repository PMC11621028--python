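"""Somatic SNV filtering over a candidate-variant count table.

Candidates from de novo pileup calling are whittled down by a cascade of
pure predicates, so the surviving set is the intersection of the rules:

1. not a known germline SNP (population panel membership);
2. genic (intergenic reads in 3'/5' capture data are mostly artifacts);
3. no germline evidence in normal spots — zero variant reads in every
   normal spot AND enough normal coverage (total >= 15 by default) to
   have detected a germline allele;
4. enough somatic signal — pooled variant count >= 5 and pooled variant
   allele frequency > 0.3 in tumor spots (tumor proportion >= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VariantTable", "filter_somatic"]


@dataclass
class VariantTable:
    sites: pd.DataFrame  # chrom, pos, ref, alt, known_germline, genic
    alt_counts: np.ndarray  # variant x spot
    total_counts: np.ndarray  # variant x spot

    def __post_init__(self):
        if (self.alt_counts > self.total_counts).any():
            raise ValueError("variant count exceeds total count")
        if self.alt_counts.shape != self.total_counts.shape:
            raise ValueError("count matrices disagree")
        if len(self.sites) != self.alt_counts.shape[0]:
            raise ValueError("site table length != count rows")


def filter_somatic(
    vt: VariantTable,
    theta: np.ndarray,
    min_alt: int = 5,
    min_vaf: float = 0.3,
    normal_depth_min: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the somatic filter cascade.

    Returns ``(somatic, annotated)``: the surviving sites, and the full
    table with per-rule pass flags and pooled tumor statistics."""
    if theta is None:
        raise ValueError("tumor proportions required")
    theta = np.asarray(theta, float)
    normal = theta < 0.5
    tumor = ~normal

    alt_n = vt.alt_counts[:, normal]
    tot_n = vt.total_counts[:, normal]
    alt_t = vt.alt_counts[:, tumor].sum(axis=1)
    tot_t = vt.total_counts[:, tumor].sum(axis=1)

    not_germline_panel = ~vt.sites["known_germline"].to_numpy(bool)
    genic = vt.sites["genic"].to_numpy(bool)
    no_normal_alt = (alt_n == 0).all(axis=1)
    normal_covered = tot_n.sum(axis=1) >= normal_depth_min
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_t = np.where(tot_t > 0, alt_t / np.maximum(tot_t, 1), 0.0)
    somatic_signal = (alt_t >= min_alt) & (vaf_t > min_vaf)

    keep = not_germline_panel & genic & no_normal_alt & normal_covered & somatic_signal
    out = vt.sites.copy()
    out["tumor_alt"] = alt_t
    out["tumor_total"] = tot_t
    out["tumor_vaf"] = vaf_t
    out["pass_panel"] = not_germline_panel
    out["pass_genic"] = genic
    out["pass_normal"] = no_normal_alt & normal_covered
    out["pass_signal"] = somatic_signal
    out["somatic"] = keep
    return out[out["somatic"]].reset_index(drop=True), out
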