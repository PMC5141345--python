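"""Consensus structural-rearrangement detection from dual call sets + alignments.

The decision rules mirror the study pipeline: two independent callers' calls
are merged when both breakends agree within 1 kb; merged candidates are
validated when at least one breakend lies in the gene body and they carry at
least ten discordant read pairs and ten split reads; and a sample whose
candidates are *all* deletions coinciding with annotated splice sites is
flagged as cDNA-contaminated and reported rearrangement-negative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pysam

from .errors import InputError
from .genome import (
    BreakFusionJunction,
    Breakend,
    GenomicInterval,
    Orientation,
)

__all__ = [
    "SvCall",
    "GsrEvent",
    "JunctionEvidence",
    "extract_support",
    "scan_junction_evidence",
    "merge_callsets",
    "filter_candidates",
    "flag_cdna_contamination",
]

#: validation thresholds: at least this many supporting pairs and split reads
MIN_PE_SUPPORT = 10
MIN_SR_SUPPORT = 10


@dataclass
class SvCall:
    """A structural-variant call from one caller."""

    caller: str
    junction: BreakFusionJunction
    qual: Optional[float] = None
    precise: bool = False


@dataclass
class GsrEvent:
    """A (candidate or validated) gene structural rearrangement in one sample."""

    sample: str
    junction: BreakFusionJunction
    pe_support: int = 0
    sr_support: int = 0
    in_gene_body: bool = False
    status: str = "candidate"
    vaf: Optional[float] = None

    @property
    def svclass(self) -> str:
        return self.junction.svclass


@dataclass
class JunctionEvidence:
    """Read-level evidence for one junction, with fragments deduplicated."""

    pe_qnames: Set[str]
    sr_qnames: Set[str]
    spanning_left: int
    spanning_right: int

    @property
    def pe_support(self) -> int:
        return len(self.pe_qnames)

    @property
    def sr_support(self) -> int:
        return len(self.sr_qnames)

    @property
    def supporting_fragments(self) -> int:
        return len(self.pe_qnames | self.sr_qnames)

    @property
    def spanning_reference(self) -> float:
        return 0.5 * (self.spanning_left + self.spanning_right)


_CIG_REF = re.compile(r"(\d+)([MIDNSHP=X])")


def _sa_ref_span(cigar: str) -> Tuple[int, int, int]:
    """(ref_len, left_clip, right_clip) of a CIGAR string."""
    ref = 0
    clips = []
    ops = _CIG_REF.findall(cigar)
    for n, op in ops:
        if op in "MDN=X":
            ref += int(n)
    left = int(ops[0][0]) if ops and ops[0][1] in "SH" else 0
    right = int(ops[-1][0]) if ops and ops[-1][1] in "SH" else 0
    return ref, left, right


def _breakend_edge_match(
    chrom: str, start: int, end: int, be: Breakend, side: str, tol: int
) -> bool:
    """Does an alignment's junction-side edge fall within ``tol`` of ``be``?

    For the left breakend of a junction, forward orientation means the
    retained sequence approaches ``pos`` from below, so the junction-side
    edge is the alignment *end*; for the right breakend, forward means the
    derivative continues upward from ``pos``, so the edge is the alignment
    *start* (and vice versa for reverse orientations).
    """
    if chrom != be.chrom:
        return False
    end_side = (side == "left") == (be.orient is Orientation.FORWARD)
    edge = (end - 1) if end_side else start
    return abs(edge - be.pos) <= tol


def _flank_match(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    be: Breakend,
    side: str,
    tol: int,
    win: int,
) -> bool:
    """Does a non-split mate lie on the retained flank of ``be``, reading toward it?"""
    if chrom != be.chrom:
        return False
    end_side = (side == "left") == (be.orient is Orientation.FORWARD)
    if end_side:
        # retained flank is below pos; the mate reads toward it on '+'
        return strand == "+" and be.pos - win <= (end - 1) <= be.pos + tol
    return strand == "-" and be.pos - tol <= start <= be.pos + win


def scan_junction_evidence(
    sam_path,
    junction: BreakFusionJunction,
    min_mapq: int = 20,
    sr_tol: int = 10,
    insert_mean: float = 300.0,
    insert_sd: float = 50.0,
    anchor: int = 20,
) -> JunctionEvidence:
    """One streaming pass over a coordinate-sorted SAM collecting junction evidence.

    Split-read support comes from primary alignments whose SA (supplementary)
    chain places alignment edges at both breakends within ``sr_tol``.
    Paired-end support comes from discordant pairs whose primary alignments
    flank the two breakends in junction-consistent orientations (a pair may
    contribute to both counts; :class:`JunctionEvidence` deduplicates
    fragments by read name).  Reference-spanning fragments are concordant
    SA-free pairs whose outer span covers a breakend with at least ``anchor``
    bases on each side; reads with mapping quality below ``min_mapq`` and
    duplicate-flagged reads are ignored throughout.
    """
    L, R = junction.left, junction.right
    win = int(insert_mean + 4 * insert_sd)
    max_insert = win
    pe: Set[str] = set()
    sr: Set[str] = set()
    span_l = span_r = 0
    pending: Dict[str, Tuple[str, int, int, str, bool]] = {}
    last_pos: Dict[str, int] = {}

    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_start < last_pos.get(rec.reference_name, -1):
                raise InputError(f"{sam_path}: alignments are not coordinate-sorted")
            last_pos[rec.reference_name] = rec.reference_start
            if rec.is_duplicate or rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            start, end = rec.reference_start, rec.reference_end
            strand = "-" if rec.is_reverse else "+"
            has_sa = rec.has_tag("SA")

            if has_sa:
                alns = [(chrom, start, end)]
                for entry in rec.get_tag("SA").rstrip(";").split(";"):
                    c, p, st, cig, mq, _nm = entry.split(",")
                    if int(mq) < min_mapq:
                        continue
                    ref_len, _, _ = _sa_ref_span(cig)
                    alns.append((c, int(p) - 1, int(p) - 1 + ref_len))
                matched_l = [
                    i
                    for i, (c, s, e) in enumerate(alns)
                    if _breakend_edge_match(c, s, e, L, "left", sr_tol)
                ]
                matched_r = [
                    i
                    for i, (c, s, e) in enumerate(alns)
                    if _breakend_edge_match(c, s, e, R, "right", sr_tol)
                ]
                if any(i != j for i in matched_l for j in matched_r):
                    sr.add(rec.query_name)

            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = (chrom, start, end, strand, has_sa)
                continue
            mchrom, mstart, mend, mstrand, mate_sa = mate
            same = mchrom == chrom
            outer_lo = min(start, mstart) if same else None
            outer_hi = max(end, mend) if same else None
            # a pair with a split mate is junction evidence, never a
            # reference-spanning fragment
            concordant = (
                same
                and not has_sa
                and not mate_sa
                and mstrand != strand
                and (outer_hi - outer_lo) <= max_insert
            )
            if concordant:
                if L.chrom == chrom and outer_lo + anchor <= L.pos < outer_hi - anchor:
                    span_l += 1
                if R.chrom == chrom and outer_lo + anchor <= R.pos < outer_hi - anchor:
                    span_r += 1
                continue
            m1 = (chrom, start, end, strand)
            m2 = (mchrom, mstart, mend, mstrand)
            for a, b in ((m1, m2), (m2, m1)):
                if _flank_match(
                    a[0], a[1], a[2], a[3], L, "left", sr_tol, win
                ) and _flank_match(b[0], b[1], b[2], b[3], R, "right", sr_tol, win):
                    pe.add(rec.query_name)
                    break
    return JunctionEvidence(pe, sr, span_l, span_r)


def extract_support(
    junction: BreakFusionJunction, sam_path, **kwargs
) -> Tuple[int, int]:
    """(paired-end, split-read) support counts for a junction; see scan_junction_evidence."""
    ev = scan_junction_evidence(sam_path, junction, **kwargs)
    return ev.pe_support, ev.sr_support


# ---------------------------------------------------------------------------
# consensus merging and filtering


def merge_callsets(
    set_a: Sequence[SvCall],
    set_b: Sequence[SvCall],
    max_dist: int = 1000,
    sample: str = "sample",
) -> List[GsrEvent]:
    """Merge two callers' call sets into consensus candidates.

    A pair merges iff chromosomes and rearrangement class agree and *both*
    breakend distances are within ``max_dist`` (inclusive).  Matching is
    one-to-one, greedy by smallest summed breakend distance with ties broken
    by lower coordinate; consensus coordinates come from a split-read-precise
    call when one is flagged, else from the first call set.  Calls supported
    by only one caller are dropped.
    """
    labels = {c.caller for c in set_a} | {c.caller for c in set_b}
    if len(labels) > 2:
        raise InputError(f"expected exactly two caller labels, got {sorted(labels)}")

    pairs = []
    for ia, a in enumerate(set_a):
        for ib, b in enumerate(set_b):
            ja, jb = a.junction, b.junction
            if (ja.left.chrom, ja.right.chrom) != (jb.left.chrom, jb.right.chrom):
                continue
            if ja.svclass != jb.svclass:
                continue
            dl = abs(ja.left.pos - jb.left.pos)
            dr = abs(ja.right.pos - jb.right.pos)
            if dl <= max_dist and dr <= max_dist:
                pairs.append((dl + dr, ja.left.pos, ja.right.pos, ia, ib))
    pairs.sort()
    used_a: Set[int] = set()
    used_b: Set[int] = set()
    out: List[GsrEvent] = []
    for _, _, _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        a, b = set_a[ia], set_b[ib]
        if a.precise:
            consensus = a.junction
        elif b.precise:
            consensus = b.junction
        else:
            consensus = a.junction
        out.append(GsrEvent(sample=sample, junction=consensus, status="candidate"))
    out.sort(key=lambda e: (e.junction.left.chrom, e.junction.left.pos))
    return out


def filter_candidates(
    candidates: Sequence[GsrEvent],
    gene_body: GenomicInterval,
    min_pe: int = MIN_PE_SUPPORT,
    min_sr: int = MIN_SR_SUPPORT,
) -> List[GsrEvent]:
    """Keep candidates with a breakend in the gene body and sufficient support.

    Support counts must already be attached (see :func:`extract_support`).
    Returns the validated events; every input event's ``in_gene_body`` and
    ``status`` fields are updated in place.
    """
    validated = []
    for ev in candidates:
        j = ev.junction
        ev.in_gene_body = gene_body.contains(j.left.chrom, j.left.pos) or gene_body.contains(
            j.right.chrom, j.right.pos
        )
        ok = ev.in_gene_body and ev.pe_support >= min_pe and ev.sr_support >= min_sr
        ev.status = "validated" if ok else "filtered"
        if ok:
            validated.append(ev)
    return validated


def flag_cdna_contamination(
    candidates: Sequence[GsrEvent],
    exons: Sequence[Tuple[GenomicInterval, str]],
    tol: int = 5,
) -> Tuple[bool, List[bool]]:
    """Detect the cDNA-contamination signature in one sample's candidates.

    A candidate is splice-coincident iff it is a deletion whose left breakend
    is within ``tol`` of an annotated exon end (splice donor) and whose right
    breakend is within ``tol`` of an annotated exon start (splice acceptor).
    The sample is flagged contaminated iff it has at least one candidate and
    *all* candidates are splice-coincident; flagged samples are to be
    reported rearrangement-negative.
    """
    donors = [iv.end - 1 for iv, _ in exons]  # last exonic base
    acceptors = [iv.start for iv, _ in exons]
    chroms = {iv.chrom for iv, _ in exons}

    flags: List[bool] = []
    for ev in candidates:
        j = ev.junction
        coincident = (
            j.svclass == "deletion"
            and j.left.chrom in chroms
            and any(abs(j.left.pos - d) <= tol for d in donors)
            and any(abs(j.right.pos - a) <= tol for a in acceptors)
        )
        flags.append(coincident)
    contaminated = bool(flags) and all(flags)
    return contaminated, flags
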