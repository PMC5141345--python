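"""Helpers for crafting small plain-text SAM files with exact read geometry."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple


def sam_text(contigs: Dict[str, int], records: Sequence[tuple]) -> str:
    """Records are raw SAM field tuples; output is coordinate-sorted with header."""
    order = {c: i for i, c in enumerate(contigs)}
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    body = sorted(records, key=lambda r: (order[r[2]], r[3]))
    for r in body:
        fields = list(map(str, r[:9])) + [r[9], r[10]] + list(r[11:])
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def proper_pair(
    qname: str,
    chrom: str,
    start1: int,
    start2: int,
    rl: int = 100,
    mapq: int = 60,
    seq1: Optional[str] = None,
    seq2: Optional[str] = None,
) -> List[tuple]:
    """A concordant FR pair: mate1 forward at start1, mate2 reverse at start2."""
    tlen = start2 + rl - start1
    s1 = seq1 or "A" * rl
    s2 = seq2 or "A" * rl
    q = "I" * rl
    return [
        (qname, 99, chrom, start1 + 1, mapq, f"{rl}M", "=", start2 + 1, tlen, s1, q),
        (qname, 147, chrom, start2 + 1, mapq, f"{rl}M", "=", start1 + 1, -tlen, s2, q),
    ]


def split_read_pair(
    qname: str,
    chrom_l: str,
    left_end: int,  # last aligned base of the left piece (0-based)
    chrom_r: str,
    right_start: int,  # first aligned base of the right piece (0-based)
    rl: int = 100,
    left_len: int = 60,
    mapq: int = 60,
    mate_start: Optional[int] = None,
) -> List[tuple]:
    """A read split across a junction (primary + supplementary) plus a mate
    mapped beyond the right breakend."""
    right_len = rl - left_len
    q = "I" * rl
    seq = "A" * rl
    p_start = left_end - left_len + 1
    sa_primary = f"SA:Z:{chrom_r},{right_start + 1},+,{left_len}S{right_len}M,{mapq},0;"
    sa_supp = f"SA:Z:{chrom_l},{p_start + 1},+,{left_len}M{right_len}S,{mapq},0;"
    mstart = right_start + 150 if mate_start is None else mate_start
    return [
        (qname, 97, chrom_l, p_start + 1, mapq, f"{left_len}M{right_len}S", chrom_r,
         mstart + 1, 0, seq, q, sa_primary),
        (qname, 97 | 2048, chrom_r, right_start + 1, mapq, f"{left_len}S{right_len}M",
         chrom_r, mstart + 1, 0, seq, q, sa_supp),
        (qname, 145, chrom_r, mstart + 1, mapq, f"{rl}M", chrom_l, p_start + 1, 0,
         "A" * rl, q),
    ]


def discordant_pair(
    qname: str,
    chrom_l: str,
    end1: int,  # last aligned base of forward mate (0-based)
    chrom_r: str,
    start2: int,  # first aligned base of reverse mate (0-based)
    rl: int = 100,
    mapq: int = 60,
) -> List[tuple]:
    """A pair flanking a junction: forward mate ending at end1, reverse mate at start2."""
    q = "I" * rl
    rnext = "=" if chrom_l == chrom_r else chrom_r
    rprev = "=" if chrom_l == chrom_r else chrom_l
    return [
        (qname, 97, chrom_l, end1 - rl + 2, mapq, f"{rl}M", rnext, start2 + 1, 0,
         "A" * rl, q),
        (qname, 145, chrom_r, start2 + 1, mapq, f"{rl}M", rprev, end1 - rl + 2, 0,
         "A" * rl, q),
    ]


def spliced_read(
    qname: str,
    chrom: str,
    start: int,
    blocks: Sequence[Tuple[int, int]],  # (aligned length, following gap) pairs
    mapq: int = 60,
) -> List[tuple]:
    """A single spliced alignment; ``blocks`` is [(M len, N len), ..., (M len, 0)]."""
    cigar = ""
    rl = 0
    for m, n in blocks:
        cigar += f"{m}M"
        rl += m
        if n:
            cigar += f"{n}N"
    return [
        (qname, 0, chrom, start + 1, mapq, cigar, "*", 0, 0, "A" * rl, "I" * rl)
    ]
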