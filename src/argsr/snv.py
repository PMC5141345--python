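"""Pileup-based SNV calling under two threshold rule sets and their consensus.

The two rule sets reproduce the decision thresholds of the study's dual-caller
scheme on plain pileup counts: rule set A requires at least three variant
reads, 10% variant fraction and total depth of 20; rule set B filters the
pileup at mapping quality 5 and requires a 1% variant fraction.  Sites called
by both rule sets are the bona fide mutations, with the reported VAF taken
from rule set A.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pysam

from .genome import GenomicInterval

__all__ = [
    "SnvCall",
    "pileup_counts",
    "call_ruleset_a",
    "call_ruleset_b",
    "consensus_snvs",
    "write_snv_vcf",
]


@dataclass(frozen=True)
class SnvCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    rule_set: str

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def pileup_counts(
    sam_path,
    region: GenomicInterval,
    min_mapq: int = 20,
) -> Dict[int, Counter]:
    """Per-position base counts over a region from primary, non-duplicate reads."""
    counts: Dict[int, Counter] = defaultdict(Counter)
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
                or rec.mapping_quality < min_mapq
                or rec.reference_name != region.chrom
            ):
                continue
            if rec.reference_end <= region.start or rec.reference_start >= region.end:
                continue
            seq = rec.query_sequence
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                if region.start <= rpos < region.end:
                    counts[rpos][seq[qpos]] += 1
    return counts


def _calls_from_pileup(
    counts: Mapping[int, Counter],
    reference: Mapping[str, str],
    region: GenomicInterval,
    rule_set: str,
    min_alt_reads: int,
    min_vaf: float,
    min_depth: int,
) -> List[SnvCall]:
    out: List[SnvCall] = []
    ref_seq = reference[region.chrom]
    for pos in sorted(counts):
        column = counts[pos]
        depth = sum(column.values())
        if depth < min_depth:
            continue
        ref_base = ref_seq[pos].upper()
        for alt, n in sorted(column.items()):
            if alt == ref_base or alt == "N":
                continue
            vaf = n / depth
            if n >= min_alt_reads and vaf >= min_vaf:
                out.append(
                    SnvCall(region.chrom, pos, ref_base, alt, depth, n, vaf, rule_set)
                )
    return out


def call_ruleset_a(
    sam_path, region: GenomicInterval, reference: Mapping[str, str]
) -> List[SnvCall]:
    """Rule set A: >=3 variant reads, >=10% of total reads, total depth >=20."""
    counts = pileup_counts(sam_path, region, min_mapq=20)
    return _calls_from_pileup(counts, reference, region, "A", 3, 0.10, 20)


def call_ruleset_b(
    sam_path, region: GenomicInterval, reference: Mapping[str, str]
) -> List[SnvCall]:
    """Rule set B: pileup filtered at mapping quality >=5, variant >=1% of reads."""
    counts = pileup_counts(sam_path, region, min_mapq=5)
    return _calls_from_pileup(counts, reference, region, "B", 1, 0.01, 1)


def consensus_snvs(a: Sequence[SnvCall], b: Sequence[SnvCall]) -> List[SnvCall]:
    """Sites called under both rule sets; VAF and counts reported from rule set A."""
    keys_b = {c.key for c in b}
    return [c for c in a if c.key in keys_b]


def write_snv_vcf(path, calls: Sequence[SnvCall]) -> None:
    """Minimal VCF with DP/AD/AF info fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"DP={c.depth};AD={c.alt_reads};AF={c.vaf:.4f}\n"
            )
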