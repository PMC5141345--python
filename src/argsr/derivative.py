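"""Derivative-chromosome construction, coordinate lifting and allele reconstruction.

A derivative chromosome is an ordered walk of oriented reference segments
(plus any non-templated inserted sequences at the seams) representing a
rearranged allele.  Junctions are applied *in order* to the evolving
derivative, so a breakend may legitimately fall inside a previously duplicated
copy; :func:`reconstruct_allele` searches operation orders and breakend
placements for a single-allele architecture on which every input junction
signature co-exists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import CoordinateError, JunctionApplicationError
from .genome import (
    BreakFusionJunction,
    Breakend,
    GenomicInterval,
    Orientation,
    revcomp,
)

__all__ = [
    "Segment",
    "InsertedSequence",
    "DerivativeChromosome",
    "AlleleReconstruction",
    "build_derivative",
    "reconstruct_allele",
    "combined_reference",
]


@dataclass(frozen=True)
class Segment:
    """Oriented source-genome stretch; 0-based half-open, reverse = revcomp on assembly."""

    chrom: str
    start: int
    end: int
    orientation: Orientation = Orientation.FORWARD

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CoordinateError(f"empty segment {self.chrom}:{self.start}-{self.end}")

    def length(self) -> int:
        return self.end - self.start

    def source_base(self, offset: int) -> int:
        """Source position of the derivative base at ``offset`` within this segment."""
        if self.orientation is Orientation.FORWARD:
            return self.start + offset
        return self.end - 1 - offset

    def offset_of(self, pos: int) -> int:
        if self.orientation is Orientation.FORWARD:
            return pos - self.start
        return self.end - 1 - pos


@dataclass(frozen=True)
class InsertedSequence:
    """Non-templated bases placed at a junction seam."""

    seq: str

    def length(self) -> int:
        return len(self.seq)


Piece = Union[Segment, InsertedSequence]


def _reverse_pieces(pieces: Sequence[Piece]) -> List[Piece]:
    out: List[Piece] = []
    for p in reversed(pieces):
        if isinstance(p, Segment):
            out.append(replace(p, orientation=p.orientation.flipped()))
        else:
            out.append(InsertedSequence(revcomp(p.seq)))
    return out


@dataclass
class DerivativeChromosome:
    """Ordered reference segments with a bidirectional coordinate map and mask list."""

    name: str
    pieces: List[Piece]
    mask: List[GenomicInterval] = field(default_factory=list)

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return sum(p.length() for p in self.pieces)

    @property
    def segments(self) -> List[Segment]:
        return [p for p in self.pieces if isinstance(p, Segment)]

    @property
    def inserted_seqs(self) -> List[str]:
        return [p.seq for p in self.pieces if isinstance(p, InsertedSequence)]

    def piece_offsets(self) -> List[int]:
        offs, cum = [], 0
        for p in self.pieces:
            offs.append(cum)
            cum += p.length()
        return offs

    # -- lifting --------------------------------------------------------
    def lift(self, pos: int) -> Tuple[str, int, Orientation]:
        """Map one derivative base to its source base.

        Returns ``(chrom, source_pos, orientation)``; inserted bases map to
        the pseudo-chromosome ``"<insertion>"`` with the offset inside the
        inserted sequence.
        """
        if not 0 <= pos < len(self):
            raise CoordinateError(f"derivative position {pos} outside [0, {len(self)})")
        for off, piece in zip(self.piece_offsets(), self.pieces):
            if off <= pos < off + piece.length():
                if isinstance(piece, InsertedSequence):
                    return ("<insertion>", pos - off, Orientation.FORWARD)
                return (piece.chrom, piece.source_base(pos - off), piece.orientation)
        raise AssertionError("unreachable")

    def lift_interval(
        self, start: int, end: int
    ) -> List[Tuple[GenomicInterval, Orientation]]:
        """Map a derivative interval to source intervals, split at every seam.

        Inserted-sequence stretches are skipped (they have no source locus).
        """
        if not (0 <= start < end <= len(self)):
            raise CoordinateError(f"derivative interval [{start},{end}) out of bounds")
        out: List[Tuple[GenomicInterval, Orientation]] = []
        for off, piece in zip(self.piece_offsets(), self.pieces):
            lo = max(start, off)
            hi = min(end, off + piece.length())
            if lo >= hi:
                continue
            if isinstance(piece, InsertedSequence):
                continue
            if piece.orientation is Orientation.FORWARD:
                s = piece.start + (lo - off)
                out.append((GenomicInterval(piece.chrom, s, s + hi - lo), piece.orientation))
            else:
                e = piece.end - (lo - off)
                out.append((GenomicInterval(piece.chrom, e - (hi - lo), e), piece.orientation))
        return out

    def lift_back(self, chrom: str, pos: int) -> List[Tuple[int, Orientation]]:
        """All derivative copies of a source base (>=2 inside duplications)."""
        hits: List[Tuple[int, Orientation]] = []
        for off, piece in zip(self.piece_offsets(), self.pieces):
            if isinstance(piece, Segment) and piece.chrom == chrom and piece.start <= pos < piece.end:
                hits.append((off + piece.offset_of(pos), piece.orientation))
        return hits

    # -- sequence -------------------------------------------------------
    def assemble(self, reference: Mapping[str, str]) -> str:
        chunks = []
        for piece in self.pieces:
            if isinstance(piece, InsertedSequence):
                chunks.append(piece.seq)
            else:
                seq = str(reference[piece.chrom][piece.start : piece.end]).upper()
                chunks.append(seq if piece.orientation is Orientation.FORWARD else revcomp(seq))
        return "".join(chunks)

    # -- junction bookkeeping -------------------------------------------
    def adjacencies(self) -> List[Tuple[Breakend, Breakend, str]]:
        """Non-contiguous seams of the walk as (left breakend, right breakend, inserted seq)."""
        out: List[Tuple[Breakend, Breakend, str]] = []
        segs: List[Tuple[Segment, str]] = []  # (segment, pending insertion before it)
        pending = ""
        for piece in self.pieces:
            if isinstance(piece, InsertedSequence):
                pending += piece.seq
            else:
                segs.append((piece, pending))
                pending = ""
        for (a, _), (b, ins) in zip(segs, segs[1:]):
            contiguous = (
                not ins
                and a.chrom == b.chrom
                and a.orientation == b.orientation
                and (
                    (a.orientation is Orientation.FORWARD and a.end == b.start)
                    or (a.orientation is Orientation.REVERSE and b.end == a.start)
                )
            )
            if contiguous:
                continue
            left = Breakend(
                a.chrom,
                a.end - 1 if a.orientation is Orientation.FORWARD else a.start,
                a.orientation,
            )
            right = Breakend(
                b.chrom,
                b.start if b.orientation is Orientation.FORWARD else b.end - 1,
                b.orientation,
            )
            out.append((left, right, ins))
        return out

    def contains_junction(self, junction: BreakFusionJunction) -> bool:
        """Whether the junction's signature occurs among the walk's seams."""
        want = (junction.left, junction.right, junction.inserted_seq)
        mirror = (
            Breakend(junction.right.chrom, junction.right.pos, junction.right.orient.flipped()),
            Breakend(junction.left.chrom, junction.left.pos, junction.left.orient.flipped()),
            revcomp(junction.inserted_seq),
        )
        for adj in self.adjacencies():
            if adj == want or adj == mirror:
                return True
        return False

    def seam_positions(self) -> List[int]:
        """Derivative offsets of the first base after each non-contiguous seam."""
        positions = []
        offs = self.piece_offsets()
        segs = [(o, p) for o, p in zip(offs, self.pieces) if isinstance(p, Segment)]
        adj_iter = iter(self.adjacencies())
        # recompute contiguity in step with adjacencies()
        for (o1, a), (o2, b) in zip(segs, segs[1:]):
            ins = o2 - (o1 + a.length()) > 0
            contiguous = (
                not ins
                and a.chrom == b.chrom
                and a.orientation == b.orientation
                and (
                    (a.orientation is Orientation.FORWARD and a.end == b.start)
                    or (a.orientation is Orientation.REVERSE and b.end == a.start)
                )
            )
            if not contiguous:
                positions.append(o2)
        return positions

    # -- reporting ------------------------------------------------------
    def segment_table(self):
        """Segment map as a DataFrame (derivative and source coordinates)."""
        import pandas as pd

        rows = []
        for off, piece in zip(self.piece_offsets(), self.pieces):
            if isinstance(piece, InsertedSequence):
                rows.append(
                    dict(
                        derivative_start=off,
                        derivative_end=off + piece.length(),
                        source_chrom="<insertion>",
                        source_start=0,
                        source_end=piece.length(),
                        orientation="+",
                    )
                )
            else:
                rows.append(
                    dict(
                        derivative_start=off,
                        derivative_end=off + piece.length(),
                        source_chrom=piece.chrom,
                        source_start=piece.start,
                        source_end=piece.end,
                        orientation="+" if piece.orientation is Orientation.FORWARD else "-",
                    )
                )
        return pd.DataFrame(rows)

    def write_chain(self, path) -> None:
        """Write a chain-style liftover file (derivative -> source), one chain per segment."""
        with open(path, "w") as fh:
            for i, (off, piece) in enumerate(zip(self.piece_offsets(), self.pieces)):
                if isinstance(piece, InsertedSequence):
                    continue
                strand = "+" if piece.orientation is Orientation.FORWARD else "-"
                fh.write(
                    f"chain 1000 {self.name} {len(self)} + {off} {off + piece.length()} "
                    f"{piece.chrom} {piece.end} {strand} {piece.start} {piece.end} {i + 1}\n"
                )
                fh.write(f"{piece.length()}\n\n")


def _as_window_map(
    windows: Union[GenomicInterval, Mapping[str, GenomicInterval]],
) -> Dict[str, GenomicInterval]:
    if isinstance(windows, GenomicInterval):
        return {windows.chrom: windows}
    return dict(windows)


def _locate(
    pieces: Sequence[Piece], chrom: str, pos: int, orient: Orientation
) -> List[int]:
    """Derivative offsets where source base (chrom, pos) occurs with walk sense ``orient``."""
    hits: List[int] = []
    off = 0
    for piece in pieces:
        if (
            isinstance(piece, Segment)
            and piece.chrom == chrom
            and piece.start <= pos < piece.end
            and piece.orientation is orient
        ):
            hits.append(off + piece.offset_of(pos))
        off += piece.length()
    return hits


def _coalesce(pieces: Sequence[Piece]) -> List[Piece]:
    """Merge adjacent segments that are contiguous in the source genome."""
    out: List[Piece] = []
    for p in pieces:
        if (
            out
            and isinstance(p, Segment)
            and isinstance(out[-1], Segment)
            and p.chrom == out[-1].chrom
            and p.orientation == out[-1].orientation
            and (
                (p.orientation is Orientation.FORWARD and out[-1].end == p.start)
                or (p.orientation is Orientation.REVERSE and out[-1].start == p.end)
            )
        ):
            prev = out.pop()
            if p.orientation is Orientation.FORWARD:
                out.append(replace(prev, end=p.end))
            else:
                out.append(replace(prev, start=p.start))
        else:
            out.append(p)
    return out


def _slice_pieces(pieces: Sequence[Piece], start: int, end: int) -> List[Piece]:
    """Pieces covering the derivative range [start, end)."""
    out: List[Piece] = []
    off = 0
    for piece in pieces:
        lo, hi = max(start, off), min(end, off + piece.length())
        if lo < hi:
            if isinstance(piece, InsertedSequence):
                out.append(InsertedSequence(piece.seq[lo - off : hi - off]))
            elif piece.orientation is Orientation.FORWARD:
                out.append(
                    replace(piece, start=piece.start + (lo - off), end=piece.start + (hi - off))
                )
            else:
                out.append(
                    replace(piece, start=piece.end - (hi - off), end=piece.end - (lo - off))
                )
        off += piece.length()
    return out


def _placements(
    pieces: Sequence[Piece],
    junction: BreakFusionJunction,
    windows: Dict[str, GenomicInterval],
) -> List[Tuple[int, int]]:
    """All valid (left offset, right offset) placements for applying ``junction``."""
    svclass = junction.svclass
    L, R = junction.left, junction.right
    total = sum(p.length() for p in pieces)
    out: List[Tuple[int, int]] = []
    if svclass == "deletion":
        for dl in _locate(pieces, L.chrom, L.pos, Orientation.FORWARD):
            for dr in _locate(pieces, R.chrom, R.pos, Orientation.FORWARD):
                if dl < dr:
                    out.append((dl, dr))
    elif svclass == "duplication":
        for dl in _locate(pieces, L.chrom, L.pos, Orientation.FORWARD):
            for dr in _locate(pieces, R.chrom, R.pos, Orientation.FORWARD):
                if dr <= dl:
                    out.append((dl, dr))
    elif svclass == "inversion":
        # both breakends located on forward-oriented stretches; the reversal
        # itself creates the reverse-oriented side of the junction
        for dl in _locate(pieces, L.chrom, L.pos, Orientation.FORWARD):
            for dr in _locate(pieces, R.chrom, R.pos, Orientation.FORWARD):
                if dl < dr:
                    out.append((dl, dr))
    elif svclass == "translocation":
        if R.chrom not in windows:
            return []
        win = windows[R.chrom]
        if not (win.start <= R.pos < win.end):
            return []
        for dl in _locate(pieces, L.chrom, L.pos, Orientation.FORWARD):
            out.append((dl, -1))
    return sorted(out)


def _apply(
    pieces: Sequence[Piece],
    junction: BreakFusionJunction,
    placement: Tuple[int, int],
    windows: Dict[str, GenomicInterval],
) -> List[Piece]:
    svclass = junction.svclass
    dl, dr = placement
    total = sum(p.length() for p in pieces)
    ins = [InsertedSequence(junction.inserted_seq)] if junction.inserted_seq else []
    if svclass == "deletion":
        return _coalesce(
            _slice_pieces(pieces, 0, dl + 1) + ins + _slice_pieces(pieces, dr, total)
        )
    if svclass == "duplication":
        return _coalesce(
            _slice_pieces(pieces, 0, dl + 1)
            + ins
            + _slice_pieces(pieces, dr, dl + 1)
            + _slice_pieces(pieces, dl + 1, total)
        )
    if svclass == "inversion":
        if junction.left.orient is Orientation.FORWARD:
            # p (+) / q (-): reverse the stretch after p through q
            return _coalesce(
                _slice_pieces(pieces, 0, dl + 1)
                + ins
                + _reverse_pieces(_slice_pieces(pieces, dl + 1, dr + 1))
                + _slice_pieces(pieces, dr + 1, total)
            )
        # p (-) / q (+): reverse the stretch from p up to (not incl.) q
        return _coalesce(
            _slice_pieces(pieces, 0, dl)
            + _reverse_pieces(_slice_pieces(pieces, dl, dr))
            + ins
            + _slice_pieces(pieces, dr, total)
        )
    if svclass == "translocation":
        R = junction.right
        win = windows[R.chrom]
        if R.orient is Orientation.FORWARD:
            partner: Piece = Segment(R.chrom, R.pos, win.end, Orientation.FORWARD)
        else:
            partner = Segment(R.chrom, win.start, R.pos + 1, Orientation.REVERSE)
        return _coalesce(_slice_pieces(pieces, 0, dl + 1) + ins + [partner])
    raise AssertionError(svclass)


def build_derivative(
    reference: Optional[Mapping[str, str]],
    junctions: Sequence[BreakFusionJunction],
    windows: Union[GenomicInterval, Mapping[str, GenomicInterval]],
    name: str = "derivative",
) -> DerivativeChromosome:
    """Apply ``junctions`` in the given order within ``windows``.

    ``windows`` maps each involved chromosome to the source interval that may
    contribute sequence; the first window (or the window of the first
    junction's left chromosome) seeds the walk.  ``reference`` is only needed
    when the assembled sequence is requested, so coordinate-only construction
    (e.g. on full hg19 coordinates) works with ``reference=None``.

    Each junction must be applicable to the evolving derivative — e.g. a
    breakend falling inside a previously deleted region raises
    :class:`JunctionApplicationError`.  When a breakend exists in several
    copies (after a duplication) the lowest-coordinate placement is taken;
    use :func:`reconstruct_allele` to search placements instead.
    """
    wmap = _as_window_map(windows)
    if junctions:
        seed_chrom = junctions[0].left.chrom
    else:
        seed_chrom = next(iter(wmap))
    if seed_chrom not in wmap:
        raise JunctionApplicationError(f"no window declared for chromosome {seed_chrom!r}")
    win = wmap[seed_chrom]
    pieces: List[Piece] = [Segment(win.chrom, win.start, win.end, Orientation.FORWARD)]
    for junction in junctions:
        placements = _placements(pieces, junction, wmap)
        if not placements:
            raise JunctionApplicationError(
                f"junction {junction} is not applicable to the current derivative "
                "(breakend outside windows or removed by a prior event)"
            )
        pieces = _apply(pieces, junction, placements[0], wmap)
    used_chroms = {p.chrom for p in pieces if isinstance(p, Segment)}
    mask = [wmap[c] for c in sorted(used_chroms) if c in wmap]
    return DerivativeChromosome(name=name, pieces=pieces, mask=mask)


@dataclass
class AlleleReconstruction:
    """Result of searching for a single-allele architecture explaining all junctions."""

    junctions: List[BreakFusionJunction]
    consistent: bool
    operation_order: List[BreakFusionJunction]
    derivative: Optional[DerivativeChromosome]
    junction_spans: Dict[Tuple[int, int], int] = field(default_factory=dict)


_CLASS_PRIORITY = {"duplication": 0, "translocation": 1, "inversion": 2, "deletion": 3}


def reconstruct_allele(
    junctions: Sequence[BreakFusionJunction],
    reference: Optional[Mapping[str, str]],
    windows: Union[GenomicInterval, Mapping[str, GenomicInterval]],
    max_ops: int = 5,
    name: str = "reconstruction",
) -> AlleleReconstruction:
    """Search orderings and breakend placements so all junctions co-occur on one allele.

    Orderings are explored with duplications before deletions and by left
    coordinate within a class (the preferred order is tried first), and for
    each ordering every breakend placement among duplicate copies is explored
    depth-first.  A reconstruction is accepted when every input junction
    signature occurs among the seams of the final derivative.  Inconsistency
    is a result (``consistent=False``), not an error.
    """
    junctions = list(junctions)
    if not 1 <= len(junctions) <= max_ops:
        raise JunctionApplicationError(
            f"reconstruct_allele handles 1..{max_ops} junctions, got {len(junctions)}"
        )
    wmap = _as_window_map(windows)
    preferred = sorted(
        junctions, key=lambda j: (_CLASS_PRIORITY[j.svclass], j.left.pos, j.right.pos)
    )
    seed_chrom = preferred[0].left.chrom
    win = wmap[seed_chrom]

    def dfs(pieces: List[Piece], remaining: Tuple[BreakFusionJunction, ...]):
        if not remaining:
            yield pieces
            return
        head, rest = remaining[0], remaining[1:]
        for placement in _placements(pieces, head, wmap):
            yield from dfs(_apply(pieces, head, placement, wmap), rest)

    for order in itertools.permutations(preferred):
        seed: List[Piece] = [Segment(win.chrom, win.start, win.end, Orientation.FORWARD)]
        for pieces in dfs(seed, tuple(order)):
            used = {p.chrom for p in pieces if isinstance(p, Segment)}
            derivative = DerivativeChromosome(
                name=name, pieces=pieces, mask=[wmap[c] for c in sorted(used) if c in wmap]
            )
            if not all(derivative.contains_junction(j) for j in junctions):
                continue
            seams = derivative.seam_positions()
            spans = {
                (i, j): abs(a - b)
                for (i, a), (j, b) in itertools.combinations(enumerate(seams), 2)
            }
            return AlleleReconstruction(
                junctions=junctions,
                consistent=True,
                operation_order=list(order),
                derivative=derivative,
                junction_spans=spans,
            )
    return AlleleReconstruction(
        junctions=junctions, consistent=False, operation_order=[], derivative=None
    )


def combined_reference(
    reference: Mapping[str, str], derivative: DerivativeChromosome
) -> Dict[str, str]:
    """Source chromosomes with contributing windows hard-masked, plus the derivative.

    Mirrors the mapping scheme in which reads are forced onto the derivative
    by N-filling the endogenous copies of every segment it contains.
    """
    out = {c: str(s) for c, s in reference.items()}
    for iv in derivative.mask:
        if iv.chrom in out:
            s = out[iv.chrom]
            out[iv.chrom] = s[: iv.start] + "N" * (iv.end - iv.start) + s[iv.end :]
    out[derivative.name] = derivative.assemble(reference)
    return out
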