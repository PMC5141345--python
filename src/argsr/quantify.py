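"""Copy-number and variant-allele-fraction quantification.

Copy number follows the capture-panel normalization: mean locus coverage is
divided by the mean of the five control-region coverages, and the ratio of
this normalized value between a tumour and a copy-neutral reference sample is
the reported copy-number ratio (amplification = ratio above threshold).

VAF is estimated at the fragment level: junction-supporting fragments
(discordant pairs and split reads, pairs counted once) against the mean
number of concordant reference-spanning fragments at the two breakends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy.stats import binomtest

from .detect import GsrEvent, scan_junction_evidence
from .errors import NormalizationError, UndefinedVafError
from .genome import GenomicInterval

__all__ = [
    "CopyNumberProfile",
    "VafEstimate",
    "mean_coverage",
    "copy_number",
    "estimate_vaf",
]


@dataclass
class CopyNumberProfile:
    sample: str
    mean_cov_locus: float
    mean_cov_controls: Tuple[float, ...]
    normalized_locus: float
    cn_ratio_vs_reference: float
    amplified: bool


@dataclass
class VafEstimate:
    event: object
    supporting: int
    spanning_reference: float
    vaf: float
    ci95: Tuple[float, float]


def mean_coverage(
    sam_path,
    regions: Sequence[GenomicInterval],
    min_mapq: int = 20,
) -> List[float]:
    """Mean per-base depth over each region from primary, non-duplicate reads."""
    totals = [0 for _ in regions]
    by_chrom: dict = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
                or rec.mapping_quality < min_mapq
            ):
                continue
            idxs = by_chrom.get(rec.reference_name)
            if not idxs:
                continue
            for b0, b1 in rec.get_blocks():
                for i in idxs:
                    r = regions[i]
                    lo, hi = max(b0, r.start), min(b1, r.end)
                    if lo < hi:
                        totals[i] += hi - lo
    return [t / r.length() for t, r in zip(totals, regions)]


def copy_number(
    sample_sam,
    locus: GenomicInterval,
    controls: Sequence[GenomicInterval],
    reference_sam,
    sample: str = "sample",
    amp_threshold: float = 1.0,
    min_mapq: int = 20,
) -> CopyNumberProfile:
    """Normalized locus coverage ratio of a tumour versus a copy-neutral sample.

    ``normalized_locus = meanCov(locus) / mean_i meanCov(control_i)`` in each
    sample; the reported ratio divides the tumour's value by the reference
    sample's.  The amplified flag is strict (> ``amp_threshold``).
    """
    regions = [locus, *controls]
    cov_s = mean_coverage(sample_sam, regions, min_mapq=min_mapq)
    cov_r = mean_coverage(reference_sam, regions, min_mapq=min_mapq)
    for label, covs in (("sample", cov_s), ("reference", cov_r)):
        if any(c <= 0 for c in covs[1:]):
            raise NormalizationError(f"zero coverage in a control region of the {label}")
    norm_s = cov_s[0] / float(np.mean(cov_s[1:]))
    norm_r = cov_r[0] / float(np.mean(cov_r[1:]))
    if norm_r == 0:
        raise NormalizationError("reference sample has zero normalized locus coverage")
    ratio = norm_s / norm_r
    return CopyNumberProfile(
        sample=sample,
        mean_cov_locus=cov_s[0],
        mean_cov_controls=tuple(cov_s[1:]),
        normalized_locus=norm_s,
        cn_ratio_vs_reference=ratio,
        amplified=ratio > amp_threshold,
    )


def estimate_vaf(event: GsrEvent, sam_path, **scan_kwargs) -> VafEstimate:
    """Fragment-level VAF of a junction with a binomial 95% interval.

    supporting / (supporting + spanning), where ``spanning`` is the mean of
    the concordant reference-spanning fragment counts at the two breakends
    and supporting fragments are deduplicated by read name.
    """
    ev = scan_junction_evidence(sam_path, event.junction, **scan_kwargs)
    supporting = ev.supporting_fragments
    spanning = ev.spanning_reference
    total = supporting + spanning
    if total <= 0:
        raise UndefinedVafError(
            f"no fragments at junction {event.junction}; VAF undefined"
        )
    vaf = supporting / total
    n = supporting + int(round(spanning))
    if n > 0:
        ci = binomtest(min(supporting, n), n).proportion_ci(0.95, method="exact")
        ci95 = (float(ci.low), float(ci.high))
    else:
        ci95 = (0.0, 1.0)
    return VafEstimate(
        event=event,
        supporting=supporting,
        spanning_reference=spanning,
        vaf=vaf,
        ci95=ci95,
    )
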