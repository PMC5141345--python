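"""Core coordinate, breakend and break-fusion-junction types.

Internally every coordinate is 0-based half-open; positions printed or parsed
at I/O boundaries (hg19-style region strings, breakend notation) are 1-based
inclusive.  A break fusion junction (BFJ) is the novel adjacency created by a
rearrangement: two oriented breakends plus an optional non-templated inserted
sequence.

Breakend semantics
------------------
On the *left* breakend, ``forward`` means the derivative retains reference
sequence approaching ``pos`` from lower coordinates (``pos`` is the last
retained base); ``reverse`` means it approaches from higher coordinates on the
reverse-complement strand.  On the *right* breakend, ``forward`` means the
derivative continues from ``pos`` toward higher coordinates; ``reverse`` means
it continues toward lower coordinates on the reverse complement.  Under this
convention the four rearrangement classes fall out of the breakend geometry
(see :func:`classify_junction`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .errors import CoordinateError, DegenerateJunctionError, NotationParseError

__all__ = [
    "Orientation",
    "GenomicInterval",
    "Breakend",
    "BreakFusionJunction",
    "JunctionSignature",
    "NotationStyle",
    "classify_junction",
    "annotate_signature",
    "parse_breakend_notation",
    "format_breakend_notation",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Unicode minus sign as printed in the source tables.
_MINUS = "−"

_VALID_INS = re.compile(r"^[ACGTN]*$")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"

    @property
    def symbol(self) -> str:
        return "+" if self is Orientation.FORWARD else _MINUS

    def flipped(self) -> "Orientation":
        return Orientation.REVERSE if self is Orientation.FORWARD else Orientation.FORWARD


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_region_string(cls, text: str) -> "GenomicInterval":
        """Parse a 1-based inclusive region string like ``chrX:66763873-66950461``."""
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise NotationParseError(f"cannot parse region string {text!r}")
        chrom = m.group(1)
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        return cls(chrom, start1 - 1, end1)

    def to_region_string(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


#: AR gene body (RefSeq NM_000044.3) on hg19, the default gene-body filter.
AR_GENE_BODY = GenomicInterval.from_region_string("chrX:66763873-66950461")

#: Default copy-number control regions from the capture panel (hg19).
CONTROL_REGIONS = tuple(
    GenomicInterval.from_region_string(s)
    for s in (
        "chr9:98258995-98264381",
        "chrX:16153017-16159789",
        "chr14:105249980-105255049",
        "chr15:40514992-40520036",
        "chr15:67390102-67395049",
    )
)


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a break fusion junction: chromosome, 0-based position, orientation."""

    chrom: str
    pos: int
    orient: Orientation = Orientation.FORWARD

    def printed_pos(self) -> int:
        return self.pos + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.printed_pos():,} ({self.orient.symbol})"


@dataclass(frozen=True)
class NotationStyle:
    """Formatting quirks recorded by the parser so notation round-trips exactly."""

    right_chrom_omitted: bool = False
    left_orient_omitted: bool = False
    right_orient_omitted: bool = False


@dataclass(frozen=True)
class BreakFusionJunction:
    """Atomic rearrangement record: two oriented breakends + optional insertion."""

    left: Breakend
    right: Breakend
    inserted_seq: str = ""
    pe_support: int = 0
    sr_support: int = 0
    style: Optional[NotationStyle] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not _VALID_INS.fullmatch(self.inserted_seq):
            raise NotationParseError(
                f"inserted sequence {self.inserted_seq!r} contains non-ACGTN characters"
            )
        # svclass consistency is enforced by computing it on demand
        classify_junction(self.left, self.right)

    @property
    def svclass(self) -> str:
        return classify_junction(self.left, self.right)

    def with_support(self, pe: int, sr: int) -> "BreakFusionJunction":
        return replace(self, pe_support=pe, sr_support=sr)

    def __str__(self) -> str:
        return format_breakend_notation(self)


@dataclass(frozen=True)
class JunctionSignature:
    """NHEJ-style signature of a junction: microhomology vs non-templated bases.

    Under the left-aligned convention an ambiguous junction is reported at its
    lowest-coordinate placement and the ambiguity span is the microhomology
    length; a junction with inserted sequence has zero microhomology by
    construction, so the two lengths are never both positive.
    """

    junction: BreakFusionJunction
    microhomology_len: int
    nontemplated_len: int
    repeat_context: str = "none"


def classify_junction(left: Breakend, right: Breakend) -> str:
    """Classify a junction as deletion / duplication / inversion / translocation.

    Different chromosomes give a translocation; on one chromosome exactly one
    reverse orientation gives an inversion boundary; two forward breakends give
    a deletion when ``left.pos < right.pos`` (sequence between them is lost)
    and a tandem duplication when ``left.pos > right.pos`` (the junction walks
    back upstream).
    """
    if left.chrom != right.chrom:
        return "translocation"
    n_reverse = (left.orient is Orientation.REVERSE) + (right.orient is Orientation.REVERSE)
    if n_reverse == 1:
        return "inversion"
    if left.pos < right.pos:
        return "deletion"
    if left.pos > right.pos:
        return "duplication"
    raise DegenerateJunctionError(
        f"breakends at identical position {left.chrom}:{left.printed_pos()} with "
        "equal orientations do not define a rearrangement"
    )


def _fetch(reference: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Fetch reference bases, clamped to the chromosome bounds."""
    seq = reference[chrom]
    if isinstance(seq, (bytes, bytearray)):
        seq = seq.decode()
    start = max(start, 0)
    end = min(end, len(seq))
    if start >= end:
        return ""
    return str(seq[start:end]).upper()


def _check_bounds(reference: Mapping[str, str], be: Breakend) -> None:
    if be.chrom not in reference:
        raise CoordinateError(f"chromosome {be.chrom!r} absent from reference")
    if not 0 <= be.pos < len(reference[be.chrom]):
        raise CoordinateError(
            f"breakend {be} outside reference bounds (len {len(reference[be.chrom])})"
        )


def _left_tail(ref, be: Breakend, k: int) -> str:
    """Last k derivative bases approaching the junction from the left side."""
    if be.orient is Orientation.FORWARD:
        return _fetch(ref, be.chrom, be.pos + 1 - k, be.pos + 1)
    return revcomp(_fetch(ref, be.chrom, be.pos, be.pos + k))


def _left_continuation(ref, be: Breakend, k: int) -> str:
    """Bases that would follow the junction if the left side's walk continued."""
    if be.orient is Orientation.FORWARD:
        return _fetch(ref, be.chrom, be.pos + 1, be.pos + 1 + k)
    return revcomp(_fetch(ref, be.chrom, be.pos - k, be.pos))


def _right_head(ref, be: Breakend, k: int) -> str:
    """First k derivative bases leaving the junction on the right side."""
    if be.orient is Orientation.FORWARD:
        return _fetch(ref, be.chrom, be.pos, be.pos + k)
    return revcomp(_fetch(ref, be.chrom, be.pos - k + 1, be.pos + 1))


def _right_precursor(ref, be: Breakend, k: int) -> str:
    """Bases that would precede the junction if the right side's walk started earlier."""
    if be.orient is Orientation.FORWARD:
        return _fetch(ref, be.chrom, be.pos - k, be.pos)
    return revcomp(_fetch(ref, be.chrom, be.pos + 1, be.pos + 1 + k))


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def annotate_signature(
    junction: BreakFusionJunction,
    reference: Mapping[str, str],
    repeats: Optional[Iterable[Tuple[GenomicInterval, str]]] = None,
    max_scan: int = 100,
) -> JunctionSignature:
    """Annotate a junction's NHEJ signature from the reference flanks.

    Microhomology is the span over which the junction placement is ambiguous:
    shifting the breakpoint by up to that many bases yields the identical
    derivative sequence.  It is computed from the oriented flanks on both
    sides and reported left-aligned.  A junction carrying inserted sequence is
    unambiguous, so its microhomology is 0 and its non-templated length is the
    insertion length.
    """
    _check_bounds(reference, junction.left)
    _check_bounds(reference, junction.right)

    nontemplated = len(junction.inserted_seq)
    if nontemplated > 0:
        mh = 0
    else:
        lb, rb = junction.left, junction.right
        # shifts toward higher derivative coordinates
        a = _lcp(_left_continuation(reference, lb, max_scan), _right_head(reference, rb, max_scan))
        # shifts toward lower derivative coordinates (compare suffixes)
        b = _lcp(
            _left_tail(reference, lb, max_scan)[::-1],
            _right_precursor(reference, rb, max_scan)[::-1],
        )
        mh = a + b

    context = "none"
    if repeats is not None:
        labels = [
            label
            for iv, label in repeats
            if iv.contains(junction.left.chrom, junction.left.pos)
            or iv.contains(junction.right.chrom, junction.right.pos)
        ]
        if labels:
            context = ";".join(sorted(set(labels)))
    return JunctionSignature(junction, mh, nontemplated, context)


_SIDE_RE = re.compile(
    r"^(?:(?P<chrom>[\w.]+):)?(?P<pos>\d[\d,]*)"
    r"(?:\s*\((?P<orient>[+\-−])\))?$"
)


def parse_breakend_notation(text: str) -> BreakFusionJunction:
    """Parse breakend notation like ``chrX:66,909,163 (+)/TTTAG/chr11:79,397,735 (+)``.

    The grammar is ``chrom:pos (±)/[INS/]chrom:pos (±)``; the right-hand
    chromosome may be omitted (inherited from the left) and either orientation
    token may be missing, in which case forward is assumed and a warning is
    issued.  Printed 1-based positions are converted to the internal 0-based
    convention; the parsed record round-trips through
    :func:`format_breakend_notation`.
    """
    parts = text.strip().split("/")
    if len(parts) == 2:
        left_txt, right_txt = parts
        ins = ""
    elif len(parts) == 3:
        left_txt, ins, right_txt = parts
        ins = ins.strip().upper()
        if not ins or not _VALID_INS.fullmatch(ins):
            raise NotationParseError(f"invalid inserted-sequence token {parts[1]!r} in {text!r}")
    else:
        raise NotationParseError(f"expected 2 or 3 '/'-separated tokens in {text!r}")

    def side(token: str, *, inherit_chrom: Optional[str]) -> tuple[Breakend, bool, bool]:
        m = _SIDE_RE.fullmatch(token.strip())
        if not m:
            raise NotationParseError(f"cannot parse breakend token {token!r} in {text!r}")
        chrom = m.group("chrom")
        chrom_omitted = chrom is None
        if chrom_omitted:
            if inherit_chrom is None:
                raise NotationParseError(f"missing chromosome in breakend token {token!r}")
            chrom = inherit_chrom
        pos1 = int(m.group("pos").replace(",", ""))
        orient_omitted = m.group("orient") is None
        if orient_omitted:
            warnings.warn(
                f"orientation token missing in {token!r}; assuming forward (+)",
                stacklevel=3,
            )
            orient = Orientation.FORWARD
        else:
            orient = (
                Orientation.FORWARD if m.group("orient") == "+" else Orientation.REVERSE
            )
        return Breakend(chrom, pos1 - 1, orient), chrom_omitted, orient_omitted

    left, left_chrom_omitted, left_oo = side(left_txt, inherit_chrom=None)
    right, right_chrom_omitted, right_oo = side(right_txt, inherit_chrom=left.chrom)
    del left_chrom_omitted  # left chromosome is mandatory by the grammar
    style = NotationStyle(
        right_chrom_omitted=right_chrom_omitted,
        left_orient_omitted=left_oo,
        right_orient_omitted=right_oo,
    )
    return BreakFusionJunction(left, right, inserted_seq=ins, style=style)


def format_breakend_notation(junction: BreakFusionJunction) -> str:
    """Format a junction in the printed notation; inverse of the parser."""
    style = junction.style or NotationStyle()

    def side(be: Breakend, omit_chrom: bool, omit_orient: bool) -> str:
        prefix = "" if omit_chrom else f"{be.chrom}:"
        token = f"{prefix}{be.printed_pos():,}"
        if not omit_orient:
            token += f" ({be.orient.symbol})"
        return token

    left = side(junction.left, False, style.left_orient_omitted)
    right = side(junction.right, style.right_chrom_omitted, style.right_orient_omitted)
    if junction.inserted_seq:
        return f"{left}/{junction.inserted_seq}/{right}"
    return f"{left}/{right}"
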