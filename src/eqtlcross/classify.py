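"""Local / distant regulator classification of called eQTL.

Rather than a fixed cis-distance cutoff, classification uses the LD-informed
rule set appropriate for the long-range LD of an F2 cross:

  a. gene and eQTL interval on different chromosomes        -> distant
  b. gene span overlaps the interval (closed, partial ok)   -> local
  c. any genotyped marker (including LD-pruned / MAF-removed
     ones from the full map) strictly between them          -> distant_same_chr
  d. otherwise (marker desert between gene and interval)    -> plausible_local

Pruned markers still block the plausible-local call by default because their
positions were genotyped even though they carry no test statistic; a switch
restricts the check to kept markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gwa import EQTLRecord
from .mixedmodel import wilcoxon_rank_sum

__all__ = [
    "LOCAL",
    "PLAUSIBLE_LOCAL",
    "DISTANT_SAME_CHR",
    "DISTANT",
    "REGULATOR_CLASSES",
    "classify_regulator",
    "eqtl_gene_distance",
    "compare_classes",
]

LOCAL = "local"
PLAUSIBLE_LOCAL = "plausible_local"
DISTANT_SAME_CHR = "distant_same_chr"
DISTANT = "distant"
REGULATOR_CLASSES = (LOCAL, PLAUSIBLE_LOCAL, DISTANT_SAME_CHR, DISTANT)


def classify_regulator(eqtl: EQTLRecord, full_map: pd.DataFrame,
                       kept_only: bool = False) -> str:
    """Assign exactly one regulator class to a called eQTL.

    ``full_map`` must carry every genotyped marker with columns chrom, pos,
    status; gene coordinates must be present on the record.
    """
    if eqtl.gene_chrom is None or eqtl.gene_start is None or eqtl.gene_end is None:
        raise ValueError(f"record {eqtl.response} lacks gene annotation")
    if eqtl.gene_chrom != eqtl.chrom:
        return DISTANT
    g0, g1 = eqtl.gene_start, eqtl.gene_end
    q0, q1 = eqtl.start, eqtl.end
    if g0 <= q1 and q0 <= g1:          # closed-interval overlap, partial counts
        return LOCAL
    lo, hi = (g1, q0) if g1 < q0 else (q1, g0)
    mp = full_map
    if kept_only:
        mp = mp[mp["status"] == "kept"]
    on = mp[mp["chrom"] == eqtl.chrom]
    between = (on["pos"] > lo) & (on["pos"] < hi)
    return DISTANT_SAME_CHR if bool(between.any()) else PLAUSIBLE_LOCAL


def eqtl_gene_distance(eqtl: EQTLRecord) -> float:
    """Distance in Mb from the peak SNP to the nearest gene edge; 0 inside the
    gene span; NaN (undefined) for cross-chromosome records."""
    if eqtl.gene_chrom is None:
        raise ValueError("record lacks gene annotation")
    if eqtl.gene_chrom != eqtl.chrom:
        return float("nan")
    pk = eqtl.peak_pos
    if eqtl.gene_start <= pk <= eqtl.gene_end:
        return 0.0
    return min(abs(pk - eqtl.gene_start), abs(pk - eqtl.gene_end)) / 1e6


def compare_classes(records: list[EQTLRecord]) -> dict:
    """Wilcoxon rank-sum comparisons of local vs distant records for
    heritability and for the number of associated SNPs."""
    loc = [r for r in records if r.reg_class == LOCAL]
    dis = [r for r in records if r.reg_class == DISTANT]
    out = {}
    if len(loc) < 2 or len(dis) < 2:
        warnings.warn("need at least two records per class; comparison skipped")
        return out
    h2l = [r.h2 for r in loc if r.h2 is not None]
    h2d = [r.h2 for r in dis if r.h2 is not None]
    if len(h2l) >= 2 and len(h2d) >= 2:
        out["h2_p"] = wilcoxon_rank_sum(h2l, h2d)
    out["n_snps_p"] = wilcoxon_rank_sum([r.n_snps for r in loc],
                                        [r.n_snps for r in dis])
    return out
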