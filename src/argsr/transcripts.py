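"""Variant-transcript assembly, ORF translation and protein feature annotation.

Observed splice junctions on a derivative assembly are chained into
transcript models (one per 3'-terminal branch), translated from the
receptor's start codon, and the resulting truncated-receptor proteins are
annotated with their C-terminal extension relative to the canonical
translation, an NLS-like basic motif scan, and average molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_mw

from .derivative import DerivativeChromosome
from .errors import CycleError, InputError
from .splicing import BinSet, JunctionCall

__all__ = [
    "TranscriptModel",
    "ProteinProduct",
    "assemble_transcripts",
    "translate_orf",
    "scan_nls_like",
    "molecular_weight",
]


@dataclass
class TranscriptModel:
    """An assembled mRNA: ordered exon intervals on the derivative."""

    name: str
    exons: List[Tuple[str, int, int]]  # (label, derivative start, derivative end)
    mrna: str
    sample: str = ""

    def exon_labels(self) -> List[str]:
        return [lbl for lbl, _, _ in self.exons]


@dataclass
class ProteinProduct:
    """A translated receptor variant and its C-terminal features."""

    sequence: str
    canonical_prefix_len: int
    cterm_extension: str
    mol_weight: float
    non_stop: bool = False
    nls_like: Optional[bool] = None
    nls_motif: str = ""


def assemble_transcripts(
    calls: Sequence[JunctionCall],
    bins: BinSet,
    derivative: DerivativeChromosome,
    reference: Mapping[str, str],
    start_exon: str = "exon1",
    sample: str = "",
    terminal_extension: int = 300,
) -> List[TranscriptModel]:
    """Enumerate transcript models from observed junctions, one per terminal branch.

    A junction graph is built on exon bins (donor = bin ending at the gap
    start, acceptor = bin starting at the gap end); paths are walked from
    ``start_exon``, taking branches in order of decreasing junction read
    count (ties by lower acceptor coordinate), and each path ends at an exon
    with no outgoing junction.  An acceptor that does not coincide with an
    annotated bin start opens an unannotated terminal exon of
    ``terminal_extension`` bases.  A cyclic junction graph raises
    :class:`CycleError`.
    """
    dseq = derivative.assemble(reference)
    bin_by_start = {b.start: b for b in bins.exon_bins()}
    bin_by_end = {b.end: b for b in bins.exon_bins()}

    # edges: donor bin label -> list of (count, acceptor pos, acceptor label)
    edges: Dict[str, List[Tuple[int, int, str]]] = {}
    for call in calls:
        donor_bin = bin_by_end.get(call.donor)
        if donor_bin is None:
            continue  # junction does not leave an annotated exon boundary
        acc_bin = bin_by_start.get(call.acceptor)
        label = acc_bin.label if acc_bin else f"novel@{call.acceptor}"
        edges.setdefault(donor_bin.label, []).append(
            (call.count_case, call.acceptor, label)
        )
    for lst in edges.values():
        lst.sort(key=lambda t: (-t[0], t[1]))

    start_bins = [b for b in bins.exon_bins() if b.label == start_exon]
    if not start_bins:
        raise InputError(f"start exon {start_exon!r} not among the bins")
    start = start_bins[0]

    paths: List[List[str]] = []

    def walk(label: str, trail: List[str]) -> None:
        if label in trail:
            raise CycleError(trail[trail.index(label) :] + [label])
        trail = trail + [label]
        outgoing = edges.get(label, [])
        if not outgoing:
            paths.append(trail)
            return
        for _count, _acc, nxt in outgoing:
            walk(nxt, trail)

    walk(start.label, [])

    bin_by_label = {b.label: b for b in bins.exon_bins()}
    models: List[TranscriptModel] = []
    for i, path in enumerate(paths):
        exon_ivs: List[Tuple[str, int, int]] = []
        for label in path:
            if label in bin_by_label:
                b = bin_by_label[label]
                exon_ivs.append((label, b.start, b.end))
            else:
                acc = int(label.split("@")[1])
                exon_ivs.append((label, acc, min(acc + terminal_extension, len(derivative))))
        mrna = "".join(dseq[s:e] for _, s, e in exon_ivs)
        models.append(
            TranscriptModel(
                name=f"transcript_{i + 1}_{path[-1]}",
                exons=exon_ivs,
                mrna=mrna,
                sample=sample,
            )
        )
    return models


def translate_orf(
    model: TranscriptModel,
    start_codon_offset: int,
    canonical_protein: Optional[str] = None,
) -> ProteinProduct:
    """Translate from the start codon to the first in-frame stop.

    The reading frame is carried across splice junctions (the mRNA is already
    the spliced sequence).  ``canonical_prefix_len`` is the length of the
    longest common prefix with the canonical receptor translation, and the
    C-terminal extension is everything beyond it.  A missing in-frame stop
    returns the run-off product flagged ``non_stop``.
    """
    cds = model.mrna[start_codon_offset:]
    if cds[:3] != "ATG":
        raise InputError(
            f"no ATG at offset {start_codon_offset} of transcript {model.name!r}"
        )
    cds = cds[: len(cds) - len(cds) % 3]
    full = str(Seq(cds).translate())
    stop = full.find("*")
    non_stop = stop < 0
    protein = full if non_stop else full[:stop]
    if canonical_protein:
        prefix = 0
        for a, b in zip(protein, canonical_protein):
            if a != b:
                break
            prefix += 1
    else:
        prefix = len(protein)
    return ProteinProduct(
        sequence=protein,
        canonical_prefix_len=prefix,
        cterm_extension=protein[prefix:],
        mol_weight=molecular_weight(protein) if protein else 0.0,
        non_stop=non_stop,
    )


def scan_nls_like(
    product: ProteinProduct,
    window: int = 15,
    motif_len: int = 5,
    min_basic: int = 2,
) -> Tuple[bool, str]:
    """Scan the start of the C-terminal extension for an NLS-like basic motif.

    Looks at the first ``window`` residues downstream of the canonical prefix
    and flags the product when any ``motif_len``-residue stretch carries at
    least ``min_basic`` basic residues (K/R) — the pattern of the second half
    of a bipartite nuclear localization signal.  Returns the flag and the
    maximal-scoring window (earliest on ties); the product's ``nls_like`` and
    ``nls_motif`` fields are updated.
    """
    region = product.cterm_extension[:window]
    best_score, best_motif = -1, ""
    for i in range(0, max(len(region) - motif_len, 0) + 1):
        chunk = region[i : i + motif_len]
        if len(chunk) < motif_len and i > 0:
            break
        score = sum(c in "KR" for c in chunk)
        if score > best_score:
            best_score, best_motif = score, chunk
    flag = best_score >= min_basic
    product.nls_like = flag
    product.nls_motif = best_motif if flag else ""
    return flag, product.nls_motif


def molecular_weight(sequence: str) -> float:
    """Average molecular weight of a peptide in daltons (residues + one water)."""
    if not sequence:
        raise InputError("cannot compute the molecular weight of an empty sequence")
    return float(_bio_mw(sequence, seq_type="protein", monoisotopic=False))
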