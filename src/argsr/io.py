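"""File-format plumbing: FASTA, exon BED, BEDPE and VCF breakend call sets.

BEDPE records carry one junction per line with the inserted sequence and
support counts in extra columns.  VCF output uses standard BND bracket
notation with a mate record per breakend; on reading, mate pairs are
collapsed back to one junction and normalized so that double-reverse mirror
representations map onto the forward-dominant form used throughout the
package.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, NotationParseError
from .genome import (
    BreakFusionJunction,
    Breakend,
    GenomicInterval,
    Orientation,
    revcomp,
)

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_exon_bed",
    "read_exon_bed",
    "write_bedpe",
    "read_bedpe",
    "write_vcf_bnd",
    "read_vcf_bnd",
    "mirror_junction",
]


# ---------------------------------------------------------------------------
# FASTA / BED


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_exon_bed(path, exons: Sequence[Tuple[GenomicInterval, str]]) -> None:
    """BED6 with exon label in the name column (0-based half-open, as BED)."""
    with open(path, "w") as fh:
        for iv, name in exons:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t+\n")


def read_exon_bed(path) -> List[Tuple[GenomicInterval, str]]:
    out: List[Tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise InputError(f"BED line has <4 columns: {line!r}")
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
    return out


# ---------------------------------------------------------------------------
# BEDPE

_STRAND = {Orientation.FORWARD: "+", Orientation.REVERSE: "-"}
_ORIENT = {"+": Orientation.FORWARD, "-": Orientation.REVERSE}

_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
    "strand1\tstrand2\tsvclass\tinserted_seq\tpe_support\tsr_support\n"
)


def write_bedpe(path, junctions: Iterable[BreakFusionJunction]) -> None:
    with open(path, "w") as fh:
        fh.write(_BEDPE_HEADER)
        for i, j in enumerate(junctions):
            fh.write(
                "\t".join(
                    [
                        j.left.chrom,
                        str(j.left.pos),
                        str(j.left.pos + 1),
                        j.right.chrom,
                        str(j.right.pos),
                        str(j.right.pos + 1),
                        f"bfj_{i + 1}",
                        ".",
                        _STRAND[j.left.orient],
                        _STRAND[j.right.orient],
                        j.svclass,
                        j.inserted_seq or ".",
                        str(j.pe_support),
                        str(j.sr_support),
                    ]
                )
                + "\n"
            )


def read_bedpe(path) -> List[BreakFusionJunction]:
    out: List[BreakFusionJunction] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise InputError(f"BEDPE line has <10 columns: {line!r}")
            ins = f[11] if len(f) > 11 and f[11] != "." else ""
            pe = int(f[12]) if len(f) > 12 else 0
            sr = int(f[13]) if len(f) > 13 else 0
            out.append(
                BreakFusionJunction(
                    Breakend(f[0], int(f[1]), _ORIENT[f[8]]),
                    Breakend(f[3], int(f[4]), _ORIENT[f[9]]),
                    inserted_seq=ins,
                    pe_support=pe,
                    sr_support=sr,
                )
            )
    return out


# ---------------------------------------------------------------------------
# VCF breakend (BND) notation


def mirror_junction(j: BreakFusionJunction) -> BreakFusionJunction:
    """The same physical adjacency read from the other side of the molecule."""
    return BreakFusionJunction(
        Breakend(j.right.chrom, j.right.pos, j.right.orient.flipped()),
        Breakend(j.left.chrom, j.left.pos, j.left.orient.flipped()),
        inserted_seq=revcomp(j.inserted_seq),
        pe_support=j.pe_support,
        sr_support=j.sr_support,
    )


def _normalize(j: BreakFusionJunction) -> BreakFusionJunction:
    """Map double-reverse mirror representations back to the forward-dominant form."""
    if (
        j.left.orient is Orientation.REVERSE
        and j.right.orient is Orientation.REVERSE
    ):
        return mirror_junction(j)
    return j


def _bnd_alt(j: BreakFusionJunction) -> str:
    """ALT bracket string for the record anchored at the left breakend."""
    L, R = j.left, j.right
    if R.orient is Orientation.FORWARD:
        bracket = f"[{R.chrom}:{R.pos + 1}["
    else:
        bracket = f"]{R.chrom}:{R.pos + 1}]"
    if L.orient is Orientation.FORWARD:
        return f"N{j.inserted_seq}{bracket}"
    # anchored base approached in reverse: mate piece joins before t, with the
    # bracket direction (and any insertion) flipped to the reference strand
    if R.orient is Orientation.FORWARD:
        bracket = f"[{R.chrom}:{R.pos + 1}["
    else:
        bracket = f"]{R.chrom}:{R.pos + 1}]"
    return f"{bracket}{revcomp(j.inserted_seq)}N"


def write_vcf_bnd(
    path,
    junctions: Iterable[BreakFusionJunction],
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write junctions as BND mate pairs (two records per junction)."""
    junctions = list(junctions)
    if contig_lengths is None:
        contig_lengths = {}
        for j in junctions:
            for be in (j.left, j.right):
                contig_lengths = dict(contig_lengths)
                contig_lengths[be.chrom] = max(
                    contig_lengths.get(be.chrom, 0), be.pos + 1000
                )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate record">\n')
        fh.write('##INFO=<ID=EVENT,Number=1,Type=String,Description="Junction id">\n')
        fh.write('##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Split-read support">\n')
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, j in enumerate(junctions):
            mj = mirror_junction(j)
            for side, (rec, mate_tag) in enumerate(
                [(j, f"bnd_{i + 1}_2"), (mj, f"bnd_{i + 1}_1")]
            ):
                info = (
                    f"SVTYPE=BND;MATEID={mate_tag};EVENT=bfj_{i + 1};"
                    f"PE={j.pe_support};SR={j.sr_support}"
                )
                fh.write(
                    f"{rec.left.chrom}\t{rec.left.pos + 1}\tbnd_{i + 1}_{side + 1}\tN\t"
                    f"{_bnd_alt(rec)}\t.\t.\t{info}\n"
                )


_BND_RE = re.compile(
    r"^(?P<head>[ACGTN]*)(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)"
    r"(?P<close>[\[\]])(?P<tail>[ACGTN]*)$"
)


def parse_bnd_alt(chrom: str, pos0: int, alt: str) -> BreakFusionJunction:
    """Decode one BND ALT string into a junction (anchored breakend = left side)."""
    m = _BND_RE.fullmatch(alt)
    if not m or m.group("open") != m.group("close"):
        raise NotationParseError(f"cannot parse BND ALT {alt!r}")
    mate = Breakend(
        m.group("chrom"),
        int(m.group("pos")) - 1,
        Orientation.FORWARD if m.group("open") == "[" else Orientation.REVERSE,
    )
    head, tail = m.group("head"), m.group("tail")
    if head:  # t[p[ or t]p] : anchored base approached forward
        ins = head[1:]  # first base is the REF base
        left = Breakend(chrom, pos0, Orientation.FORWARD)
        return _normalize(BreakFusionJunction(left, mate, inserted_seq=ins))
    # ]p]t or [p[t : anchored base approached in reverse
    ins = revcomp(tail[:-1])
    left = Breakend(chrom, pos0, Orientation.REVERSE)
    return _normalize(BreakFusionJunction(left, mate, inserted_seq=ins))


def read_vcf_bnd(path) -> List[BreakFusionJunction]:
    """Read BND records, collapsing mate pairs to one junction each."""
    import pysam

    out: List[BreakFusionJunction] = []
    seen_keys = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if "[" not in alt and "]" not in alt:
                    continue
                j = parse_bnd_alt(rec.chrom, rec.pos - 1, alt)
                pe = rec.info.get("PE")
                sr = rec.info.get("SR")
                if pe is not None or sr is not None:
                    j = j.with_support(int(pe or 0), int(sr or 0))
                key_fwd = (
                    (j.left.chrom, j.left.pos, j.left.orient.value),
                    (j.right.chrom, j.right.pos, j.right.orient.value),
                    j.inserted_seq,
                )
                mj = mirror_junction(j)
                key_rev = (
                    (mj.left.chrom, mj.left.pos, mj.left.orient.value),
                    (mj.right.chrom, mj.right.pos, mj.right.orient.value),
                    mj.inserted_seq,
                )
                canon = min(key_fwd, key_rev)
                if canon in seen_keys:
                    continue
                seen_keys.add(canon)
                out.append(j)
    return out
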