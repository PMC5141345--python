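"""Splice-junction extraction, exon/intron bin matrices and tumour-specific calls.

RNA-seq reads mapped to a tumour-specific derivative assembly are reduced to
junction observations (split reads with at least 5 bp aligned on each side of
the gap), binned into the derivative's exon/intron bins (the heatmap), and
compared against a matched control sample mapped to the same assembly:
junctions that lift across a rearrangement seam and are absent from the
control are the rearrangement-dependent splicing events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

from .derivative import DerivativeChromosome, Segment
from .errors import InputError
from .genome import GenomicInterval, Orientation

__all__ = [
    "Bin",
    "BinSet",
    "SpliceJunctionMatrix",
    "JunctionCall",
    "make_bins",
    "extract_junctions",
    "junction_matrix",
    "call_rearrangement_dependent",
]


@dataclass(frozen=True)
class Bin:
    label: str
    start: int  # derivative coordinates
    end: int
    kind: str  # "exon" | "intron"


@dataclass
class BinSet:
    """Ordered exon/intron bins tiling a derivative chromosome."""

    bins: List[Bin]

    def __len__(self) -> int:
        return len(self.bins)

    def labels(self) -> List[str]:
        return [b.label for b in self.bins]

    def index_of(self, pos: int) -> Optional[int]:
        for i, b in enumerate(self.bins):
            if b.start <= pos < b.end:
                return i
        return None

    def exon_bins(self) -> List[Bin]:
        return [b for b in self.bins if b.kind == "exon"]


def make_bins(
    derivative: DerivativeChromosome,
    exons: Sequence[Tuple[GenomicInterval, str]],
) -> BinSet:
    """Exon bins for every (partial or complete) exon copy on the derivative,
    with intron bins filling the gaps, tiling the assembly without overlap.
    Later copies of an exon get a ``.2``, ``.3`` ... suffix."""
    exon_hits: List[Tuple[int, int, str]] = []
    off = 0
    for piece in derivative.pieces:
        if isinstance(piece, Segment) and piece.orientation is Orientation.FORWARD:
            for iv, label in exons:
                if iv.chrom != piece.chrom:
                    continue
                lo, hi = max(iv.start, piece.start), min(iv.end, piece.end)
                if lo < hi:
                    exon_hits.append((off + (lo - piece.start), off + (hi - piece.start), label))
        off += piece.length()
    exon_hits.sort()

    counts: Dict[str, int] = {}
    bins: List[Bin] = []
    cursor = 0
    intron_idx = 0
    total = len(derivative)
    for start, end, label in exon_hits:
        if start < cursor:
            raise InputError("overlapping exon annotations on the derivative")
        if start > cursor:
            intron_idx += 1
            bins.append(Bin(f"intron.{intron_idx}", cursor, start, "intron"))
        counts[label] = counts.get(label, 0) + 1
        suffix = "" if counts[label] == 1 else f".{counts[label]}"
        bins.append(Bin(f"{label}{suffix}", start, end, "exon"))
        cursor = end
    if cursor < total:
        intron_idx += 1
        bins.append(Bin(f"intron.{intron_idx}", cursor, total, "intron"))
    return BinSet(bins)


def extract_junctions(
    sam_path, min_overhang: int = 5
) -> Tuple[Dict[Tuple[int, int], int], int, int]:
    """Splice-junction observations from spliced alignments.

    A gap observation is retained iff the read has at least ``min_overhang``
    aligned bases on each side of that gap.  Returns
    ``(counts keyed by (donor, acceptor), retained, discarded)`` where
    ``donor`` is the first skipped base and ``acceptor`` the first aligned
    base after the gap (0-based derivative coordinates).
    """
    counts: Dict[Tuple[int, int], int] = {}
    retained = discarded = 0
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cig = rec.cigartuples
            if cig is None:
                raise InputError(f"alignment {rec.query_name} has no CIGAR")
            ref_pos = rec.reference_start
            aligned = [0]  # aligned bases per inter-gap block
            gaps: List[Tuple[int, int]] = []
            for op, n in cig:
                if op in (0, 7, 8):  # M/=/X
                    aligned[-1] += n
                    ref_pos += n
                elif op == 2:  # D
                    ref_pos += n
                elif op == 3:  # N
                    gaps.append((ref_pos, ref_pos + n))
                    aligned.append(0)
                    ref_pos += n
            for gi, (d, a) in enumerate(gaps):
                left_ok = sum(aligned[: gi + 1]) >= min_overhang
                right_ok = sum(aligned[gi + 1 :]) >= min_overhang
                if left_ok and right_ok:
                    counts[(d, a)] = counts.get((d, a), 0) + 1
                    retained += 1
                else:
                    discarded += 1
    return counts, retained, discarded


@dataclass
class SpliceJunctionMatrix:
    """Counts of junction observations between ordered bins (donor -> acceptor)."""

    bins: BinSet
    counts: np.ndarray
    retained_reads: int
    discarded_short_overhang: int
    out_of_bin: int = 0

    def to_dataframe(self):
        import pandas as pd

        labels = self.bins.labels()
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def plot_heatmap(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        fig, ax = plt.subplots(figsize=(8, 7))
        with np.errstate(divide="ignore"):
            img = ax.imshow(np.log10(df.values + 1), cmap="viridis")
        ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(df.index)), df.index, fontsize=6)
        ax.set_xlabel("second exon in junction (acceptor bin)")
        ax.set_ylabel("first exon in junction (donor bin)")
        fig.colorbar(img, ax=ax, label="log10(junction reads + 1)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def junction_matrix(
    junctions: Mapping[Tuple[int, int], int],
    bins: BinSet,
    retained: int = 0,
    discarded: int = 0,
) -> SpliceJunctionMatrix:
    """Accumulate junction observations into the (donor bin, acceptor bin) matrix."""
    n = len(bins)
    counts = np.zeros((n, n), dtype=int)
    out_of_bin = 0
    for (d, a), c in junctions.items():
        i = bins.index_of(d - 1)  # last aligned base before the gap
        j = bins.index_of(a)
        if i is None or j is None:
            out_of_bin += c
            continue
        counts[i, j] += c
    return SpliceJunctionMatrix(
        bins=bins,
        counts=counts,
        retained_reads=retained,
        discarded_short_overhang=discarded,
        out_of_bin=out_of_bin,
    )


@dataclass
class JunctionCall:
    donor: int
    acceptor: int
    count_case: int
    count_control: int
    crosses_seam: bool
    status: str  # canonical | novel | rearrangement_dependent


def call_rearrangement_dependent(
    case_junctions: Mapping[Tuple[int, int], int],
    control_junctions: Mapping[Tuple[int, int], int],
    derivative: DerivativeChromosome,
    bins: BinSet,
    min_reads: int = 3,
) -> List[JunctionCall]:
    """Classify each case junction against the matched-control sample.

    A junction crosses a seam when a rearrangement seam of the derivative
    lies between its donor and acceptor, i.e. its two sides lift to
    non-adjacent reference loci.  Seam-crossing junctions absent from the
    control are rearrangement-dependent; junctions at annotated exon
    boundaries are canonical; remaining control-absent junctions need
    ``min_reads`` case observations to be called rearrangement-dependent,
    otherwise they are reported as novel.
    """
    seams = derivative.seam_positions()
    exon_ends = {b.end for b in bins.exon_bins()}
    exon_starts = {b.start for b in bins.exon_bins()}
    out: List[JunctionCall] = []
    for (d, a), c in sorted(case_junctions.items()):
        ctrl = control_junctions.get((d, a), 0)
        crosses = any(d < s <= a for s in seams)
        if ctrl > 0:
            # shared with the matched control: not tumour-specific
            status = (
                "canonical" if (d in exon_ends and a in exon_starts) else "novel"
            )
        elif crosses or c >= min_reads:
            status = "rearrangement_dependent"
        else:
            status = "novel"
        out.append(JunctionCall(d, a, c, ctrl, crosses, status))
    return out
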