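"""Truth-annotated synthetic cohort generator.

The generator emulates the study design the analysis assumes: a targeted
capture experiment over a ~200 kb AR-like gene locus (8 canonical exons, a
cryptic exon in intron 3, four cryptic exons upstream of the gene) on one
chromosome plus a translocation-partner chromosome that also carries the
copy-number control regions.  Samples are mixtures of clones; each clone
carries an ordered list of break-fusion junctions, an integer locus copy
number and optional hotspot SNVs.  Reads are emitted pre-aligned: every read
is placed on the clone's derivative chromosome and lifted back to reference
coordinates, so read pairs straddling a junction appear as discordant pairs
and reads crossing it appear as split (supplementary) alignments with the
correct clipping — without any aligner in the loop.

Coding structure is designed so the RNA round trip is exact: every canonical
exon's coding length is a multiple of three (all splice phases are 0), the
upstream exon ``4-ups`` starts with a VRRGR motif and keeps the frame open,
the ``5a/5b/5c-ups`` and CE3 exons terminate translation with distinct
C-terminal extensions, and the partner-chromosome exon encodes a 13-residue
VGKTK-motif extension.

Every output is a pure function of the configuration and the seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .derivative import DerivativeChromosome, Segment, build_derivative
from .detect import SvCall
from .errors import ConfigurationError, CoordinateError
from .genome import (
    BreakFusionJunction,
    Breakend,
    GenomicInterval,
    Orientation,
    parse_breakend_notation,
    revcomp,
)

__all__ = [
    "SimConfig",
    "CloneSpec",
    "TranscriptSpec",
    "SampleSpec",
    "SyntheticReference",
    "SyntheticTruth",
    "SvCall",
    "make_reference",
    "simulate_dna_reads",
    "simulate_rna_reads",
    "emit_caller_callsets",
    "default_cohort",
]

_BASES = np.array(list("ACGT"))

# fixed reverse-translation table (one codon per residue, no in-frame stops)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTG",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}
_AA = "ACDEFGHIKLMNPQRSTVWY"


def _encode_peptide(pep: str) -> str:
    return "".join(_CODON[a] for a in pep)


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class SimConfig:
    """Sequencing-layer parameters of the emulated experiment."""

    seed: int = 0
    read_len_dna: int = 150
    read_len_rna: int = 50
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    rna_insert_mean: float = 160.0
    rna_insert_sd: float = 25.0
    coverage: float = 200.0
    rna_read_pairs: int = 30000
    error_rate: float = 0.0
    min_anchor: int = 20  # shortest split-alignment piece an aligner would place

    def __post_init__(self) -> None:
        if min(self.read_len_dna, self.read_len_rna) <= 0 or self.coverage <= 0:
            raise ConfigurationError("read lengths and coverage must be positive")
        if self.insert_mean <= 0 or self.insert_sd <= 0:
            raise ConfigurationError("insert-size parameters must be positive")


@dataclass
class CloneSpec:
    """One tumour sub-clone: cell fraction, ordered events, locus copy number, SNVs.

    ``snvs`` entries are ``(pos, ref, alt, dosage)`` with ``pos`` a 0-based
    position on the locus chromosome and ``dosage`` the fraction of this
    clone's locus copies carrying the variant (1.0 = clonal within the clone).
    """

    fraction: float
    events: List[BreakFusionJunction] = field(default_factory=list)
    locus_copy_number: int = 1
    snvs: List[Tuple[int, str, str, float]] = field(default_factory=list)


@dataclass
class TranscriptSpec:
    """An expressed transcript: ordered exon labels and an expression weight."""

    name: str
    exons: Tuple[str, ...]
    weight: float = 1.0


@dataclass
class SampleSpec:
    name: str
    clones: List[CloneSpec]
    transcripts: List[TranscriptSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"clone fractions of sample {self.name!r} sum to {total}, not 1"
            )


@dataclass
class SyntheticReference:
    """Reference sequences plus the designed gene architecture."""

    sequences: Dict[str, str]
    exons: List[Tuple[GenomicInterval, str]]
    gene_body: GenomicInterval
    control_regions: List[GenomicInterval]
    locus_chrom: str
    partner_chrom: str
    start_codon_offset: int  # within exon 1 / within any canonical-start mRNA
    n_exons: int

    def exon(self, label: str) -> GenomicInterval:
        for iv, name in self.exons:
            if name == label:
                return iv
        raise KeyError(label)

    def exon_labels(self) -> List[str]:
        return [name for _, name in self.exons]

    def canonical_chain(self) -> Tuple[str, ...]:
        return tuple(f"exon{i + 1}" for i in range(self.n_exons))

    def windows(self) -> Dict[str, GenomicInterval]:
        return {
            c: GenomicInterval(c, 0, len(s)) for c, s in self.sequences.items()
        }

    def mrna(self, exon_chain: Sequence[str]) -> str:
        return "".join(
            self.sequences[self.exon(lbl).chrom][
                self.exon(lbl).start : self.exon(lbl).end
            ]
            for lbl in exon_chain
        )

    def protein(self, exon_chain: Sequence[str]) -> str:
        from Bio.Seq import Seq

        cds = self.mrna(exon_chain)[self.start_codon_offset :]
        cds = cds[: len(cds) - len(cds) % 3]
        return str(Seq(cds).translate(to_stop=True))


@dataclass
class SyntheticTruth:
    """Full generative record; sufficient to recompute every expected output."""

    config: SimConfig
    reference: SyntheticReference
    samples: List[SampleSpec]

    def sample(self, name: str) -> SampleSpec:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)

    def sample_junctions(self, name: str) -> List[BreakFusionJunction]:
        seen, out = set(), []
        for clone in self.sample(name).clones:
            for j in clone.events:
                key = (j.left, j.right, j.inserted_seq)
                if key not in seen:
                    seen.add(key)
                    out.append(j)
        return out

    def expected_vaf(self, name: str, junction: BreakFusionJunction) -> float:
        """Carrier locus-copy mass over total locus-copy mass."""
        num = den = 0.0
        for clone in self.sample(name).clones:
            mass = clone.fraction * clone.locus_copy_number
            den += mass
            if any(
                (j.left, j.right, j.inserted_seq)
                == (junction.left, junction.right, junction.inserted_seq)
                for j in clone.events
            ):
                num += mass
        return num / den if den else 0.0

    def expected_snv_vaf(self, name: str, pos: int, alt: str) -> float:
        num = den = 0.0
        for clone in self.sample(name).clones:
            mass = clone.fraction * clone.locus_copy_number
            den += mass
            for p, _r, a, dosage in clone.snvs:
                if p == pos and a == alt:
                    num += mass * dosage
        return num / den if den else 0.0

    def expected_cn_ratio(self, name: str, reference_sample: str) -> float:
        def mean_cn(s: str) -> float:
            return sum(c.fraction * c.locus_copy_number for c in self.sample(s).clones)

        return mean_cn(name) / mean_cn(reference_sample)

    def clone_derivative(self, name: str, clone_index: int) -> DerivativeChromosome:
        clone = self.sample(name).clones[clone_index]
        return build_derivative(
            self.reference.sequences,
            clone.events,
            self.reference.windows(),
            name=f"der_{name}_{clone_index}",
        )

    def mapping_derivative(self, name: str) -> DerivativeChromosome:
        """The tumour-specific assembly: the first event-bearing clone's derivative."""
        for i, clone in enumerate(self.sample(name).clones):
            if clone.events:
                return self.clone_derivative(name, i)
        return self.clone_derivative(name, 0)

    # -- serialization --------------------------------------------------
    def to_json(self, path) -> None:
        def junc(j: BreakFusionJunction) -> str:
            return str(j)

        payload = {
            "config": asdict(self.config),
            "reference": {
                "sequences": self.reference.sequences,
                "exons": [
                    [iv.chrom, iv.start, iv.end, name]
                    for iv, name in self.reference.exons
                ],
                "gene_body": self.reference.gene_body.to_region_string(),
                "control_regions": [
                    c.to_region_string() for c in self.reference.control_regions
                ],
                "locus_chrom": self.reference.locus_chrom,
                "partner_chrom": self.reference.partner_chrom,
                "start_codon_offset": self.reference.start_codon_offset,
                "n_exons": self.reference.n_exons,
            },
            "samples": [
                {
                    "name": s.name,
                    "clones": [
                        {
                            "fraction": c.fraction,
                            "events": [junc(j) for j in c.events],
                            "locus_copy_number": c.locus_copy_number,
                            "snvs": [list(x) for x in c.snvs],
                        }
                        for c in s.clones
                    ],
                    "transcripts": [
                        {"name": t.name, "exons": list(t.exons), "weight": t.weight}
                        for t in s.transcripts
                    ],
                }
                for s in self.samples
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        ref = payload["reference"]
        reference = SyntheticReference(
            sequences=ref["sequences"],
            exons=[
                (GenomicInterval(c, s, e), name) for c, s, e, name in ref["exons"]
            ],
            gene_body=GenomicInterval.from_region_string(ref["gene_body"]),
            control_regions=[
                GenomicInterval.from_region_string(x) for x in ref["control_regions"]
            ],
            locus_chrom=ref["locus_chrom"],
            partner_chrom=ref["partner_chrom"],
            start_codon_offset=ref["start_codon_offset"],
            n_exons=ref["n_exons"],
        )
        samples = [
            SampleSpec(
                name=s["name"],
                clones=[
                    CloneSpec(
                        fraction=c["fraction"],
                        events=[parse_breakend_notation(t) for t in c["events"]],
                        locus_copy_number=c["locus_copy_number"],
                        snvs=[tuple(x) for x in c["snvs"]],
                    )
                    for c in s["clones"]
                ],
                transcripts=[
                    TranscriptSpec(t["name"], tuple(t["exons"]), t["weight"])
                    for t in s["transcripts"]
                ],
            )
            for s in payload["samples"]
        ]
        return cls(SimConfig(**payload["config"]), reference, samples)


# ---------------------------------------------------------------------------
# reference construction

# designed C-terminal extension peptides for the cryptic exons; 4-ups keeps
# the frame open (no stop) so 5a/5b/5c terminate the variant ORFs
_EXON_PEPTIDES = {
    "4-ups": "VRRGRAQHLS",
    "5a-ups": "GTWLE*",
    "5b-ups": "SPREALDA*",
    "5c-ups": "WGD*",
    "CE3": "EKFRVGNCKHLKMTRP*",
    "chr11x": "VGKTKSGVEDNLL*",
}


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n)


def make_reference(
    seed: int,
    locus_len: int = 200_000,
    n_exons: int = 8,
    partner_chrom_len: int = 60_000,
    upstream_len: int = 60_000,
    downstream_len: int = 20_000,
) -> SyntheticReference:
    """Deterministically build the two-chromosome reference and its annotation.

    ``chrA`` carries the gene body (``upstream_len`` bases of upstream flank,
    then ``locus_len`` of gene, then ``downstream_len`` of downstream flank)
    plus the upstream cryptic exons and the intron-3 cryptic exon CE3;
    ``chrB`` carries the translocation-partner exon and the five copy-number
    control regions.
    """
    if locus_len < 50_000:
        raise ConfigurationError("locus_len must be >= 50 kb for realistic introns")
    if n_exons < 4:
        raise ConfigurationError("need at least 4 canonical exons")
    if upstream_len < 50_000 or partner_chrom_len < 30_000:
        raise ConfigurationError("upstream/partner regions too short for the layout")

    rng = np.random.default_rng([int(seed) % (2**31), 11])
    chr_a = _random_seq(rng, upstream_len + locus_len + downstream_len)
    chr_b = _random_seq(rng, partner_chrom_len)

    utr5, utr3 = 120, 400
    coding = [1536] + [150] * (n_exons - 2) + [603]
    lengths = [utr5 + coding[0]] + coding[1:-1] + [coding[-1] + utr3]
    gene_start = upstream_len
    starts = [
        gene_start + round(0.92 * locus_len * i / (n_exons - 1)) for i in range(n_exons)
    ]
    for (s0, l0), s1 in zip(zip(starts, lengths), starts[1:]):
        if s1 - (s0 + l0) < 500:
            raise ConfigurationError("exon layout infeasible: introns would be < 500 bp")
    if starts[-1] + lengths[-1] > gene_start + locus_len:
        raise ConfigurationError("exon layout infeasible for requested locus length")

    exons: List[Tuple[GenomicInterval, str]] = []
    for i, (s, l) in enumerate(zip(starts, lengths)):
        exons.append((GenomicInterval("chrA", s, s + l), f"exon{i + 1}"))

    # canonical CDS: deterministic random protein, all splice phases 0
    n_codons = sum(coding) // 3  # includes the stop
    protein = "M" + "".join(
        _AA[i] for i in rng.integers(0, len(_AA), n_codons - 2)
    )
    cds = _encode_peptide(protein) + _CODON["*"]
    off = 0
    for i, (iv, _name) in enumerate(exons):
        lead = utr5 if i == 0 else 0
        chunk = cds[off : off + coding[i]]
        off += coding[i]
        arr = np.frombuffer(chunk.encode(), dtype="S1")
        idx = np.searchsorted(np.frombuffer(b"ACGT", dtype="S1"), arr)
        chr_a[iv.start + lead : iv.start + lead + coding[i]] = idx

    # cryptic exons: CE3 in intron 3, four exons upstream of the gene
    e3, e4 = exons[2][0], exons[3][0]
    ce3_start = (e3.end + e4.start) // 2
    cryptic: List[Tuple[str, GenomicInterval]] = [
        ("CE3", GenomicInterval("chrA", ce3_start, ce3_start + 300)),
        ("4-ups", GenomicInterval("chrA", round(0.30 * upstream_len), round(0.30 * upstream_len) + 30)),
        ("5a-ups", GenomicInterval("chrA", round(0.45 * upstream_len), round(0.45 * upstream_len) + 300)),
        ("5b-ups", GenomicInterval("chrA", round(0.60 * upstream_len), round(0.60 * upstream_len) + 300)),
        ("5c-ups", GenomicInterval("chrA", round(0.75 * upstream_len), round(0.75 * upstream_len) + 300)),
        ("chr11x", GenomicInterval("chrB", round(0.55 * partner_chrom_len), round(0.55 * partner_chrom_len) + 300)),
    ]
    base_lut = np.frombuffer(b"ACGT", dtype="S1")
    for label, iv in cryptic:
        pep = _EXON_PEPTIDES[label]
        chunk = _encode_peptide(pep)
        if len(chunk) > iv.length():
            raise ConfigurationError(f"cryptic exon {label} too short for its peptide")
        arr = np.frombuffer(chunk.encode(), dtype="S1")
        idx = np.searchsorted(base_lut, arr)
        target = chr_a if iv.chrom == "chrA" else chr_b
        target[iv.start : iv.start + len(chunk)] = idx
        exons.append((iv, label))
    exons.sort(key=lambda x: (x[0].chrom, x[0].start))

    # control regions sit below the translocation-partner region so that a
    # derivative recruiting the chrB tail never alters control coverage
    controls = [
        GenomicInterval("chrB", s, s + 3000)
        for s in (
            round(0.05 * partner_chrom_len),
            round(0.14 * partner_chrom_len),
            round(0.23 * partner_chrom_len),
            round(0.32 * partner_chrom_len),
            round(0.41 * partner_chrom_len),
        )
    ]

    sequences = {
        "chrA": "".join(_BASES[chr_a]),
        "chrB": "".join(_BASES[chr_b]),
    }
    return SyntheticReference(
        sequences=sequences,
        exons=exons,
        gene_body=GenomicInterval("chrA", gene_start, gene_start + locus_len),
        control_regions=controls,
        locus_chrom="chrA",
        partner_chrom="chrB",
        start_codon_offset=utr5,
        n_exons=n_exons,
    )


# ---------------------------------------------------------------------------
# DNA read simulation


def _sam_header(contigs: Mapping[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.append("@PG\tID:argsr-sim\tPN:argsr-sim")
    return "\n".join(lines) + "\n"


def _read_parts(deriv: DerivativeChromosome, offsets, a: int, b: int):
    """Pieces of the derivative overlapped by derivative interval [a, b)."""
    parts = []
    i = int(np.searchsorted(offsets, a, side="right")) - 1
    pos = a
    while pos < b:
        piece = deriv.pieces[i]
        off = offsets[i]
        hi = min(b, off + piece.length())
        parts.append((piece, int(off), pos, int(hi)))
        pos = hi
        i += 1
    return parts


def _alignments_for_read(deriv, offsets, a, b, sd, min_anchor):
    """Candidate alignments (one per reference-mappable piece) for a read on [a, b)."""
    rl = b - a
    alns = []
    for piece, off, lo, hi in _read_parts(deriv, offsets, a, b):
        if isinstance(piece, Segment):
            plen = hi - lo
            if piece.orientation is Orientation.FORWARD:
                src_start = piece.start + (lo - off)
                strand = sd
            else:
                src_start = piece.end - (hi - off)
                strand = "-" if sd == "+" else "+"
            r0 = lo - a if sd == "+" else b - hi
            alns.append(
                dict(
                    chrom=piece.chrom,
                    pos=src_start,
                    strand=strand,
                    r0=r0,
                    r1=r0 + plen,
                    plen=plen,
                )
            )
    alns.sort(key=lambda d: -d["plen"])
    primary = alns[0] if alns else None
    supplementary = [d for d in alns[1:] if d["plen"] >= min_anchor]
    return primary, supplementary


def _cigar(aln, rl: int) -> str:
    left = aln["r0"] if aln["strand"] == "+" else rl - aln["r1"]
    right = rl - aln["plen"] - left
    parts = []
    if left:
        parts.append(f"{left}S")
    parts.append(f"{aln['plen']}M")
    if right:
        parts.append(f"{right}S")
    return "".join(parts)


def simulate_dna_reads(
    truth: SyntheticTruth,
    sample_name: str,
    out_sam,
    out_fastq_prefix: Optional[str] = None,
    coverage: Optional[float] = None,
    stream: int = 0,
) -> Path:
    """Emit coordinate-sorted SAM (and optionally FASTQ) for one sample.

    Fragment counts per clone molecule follow the clone fraction and copy
    number: a copy-number-2 region receives the configured ``coverage``, so
    per-base depth over unrearranged locus regions scales as
    coverage x copy_number / 2 across the clone mixture.
    """
    cfg = truth.config
    ref = truth.reference
    sample = truth.sample(sample_name)
    cov = coverage if coverage is not None else cfg.coverage
    rl = cfg.read_len_dna
    rng = np.random.default_rng(
        [cfg.seed % (2**31), 101, stream, zlib.crc32(sample_name.encode()) % (2**31)]
    )

    for clone in sample.clones:
        for j in clone.events:
            for be in (j.left, j.right):
                if be.chrom not in ref.sequences or not (
                    0 <= be.pos < len(ref.sequences[be.chrom])
                ):
                    raise CoordinateError(f"event breakend {be} outside reference")

    # molecules: per clone the locus-chromosome derivative (multiplicity =
    # locus copy number) and the shared partner chromosome (multiplicity 2)
    windows = ref.windows()
    partner = DerivativeChromosome(
        name=ref.partner_chrom,
        pieces=[Segment(ref.partner_chrom, 0, len(ref.sequences[ref.partner_chrom]))],
    )
    partner_seq = ref.sequences[ref.partner_chrom]
    molecules = []  # (deriv, seq, weight, snv list [(dpos, alt, dosage)])
    for ci, clone in enumerate(sample.clones):
        if clone.events:
            deriv = build_derivative(
                ref.sequences, clone.events, windows, name=f"der_{sample_name}_{ci}"
            )
        else:
            deriv = DerivativeChromosome(
                name=ref.locus_chrom,
                pieces=[Segment(ref.locus_chrom, 0, len(ref.sequences[ref.locus_chrom]))],
            )
        seq = deriv.assemble(ref.sequences)
        snvs = []
        for pos, ref_base, alt, dosage in clone.snvs:
            for dpos, orient in deriv.lift_back(ref.locus_chrom, pos):
                snvs.append(
                    (dpos, alt if orient is Orientation.FORWARD else revcomp(alt), dosage)
                )
        molecules.append((deriv, seq, clone.fraction * clone.locus_copy_number, snvs))
        molecules.append((partner, partner_seq, clone.fraction * 2.0, []))

    contigs = {c: len(s) for c, s in ref.sequences.items()}
    order = {c: i for i, c in enumerate(contigs)}
    records: List[Tuple[int, int, str]] = []
    fastq1, fastq2 = [], []
    mean, sd = cfg.insert_mean, cfg.insert_sd
    max_insert = mean + 4 * sd
    frag_id = 0

    for deriv, seq, weight, snvs in molecules:
        L = len(seq)
        n_frag = int(rng.poisson(cov / 2.0 * weight * L / (2.0 * rl)))
        if n_frag == 0:
            continue
        offsets = np.asarray(deriv.piece_offsets())
        # truncate at 4 s.d. so every event-free fragment is concordant under
        # the standard proper-pair window
        flens = np.clip(
            np.rint(rng.normal(mean, sd, n_frag)).astype(np.int64),
            rl,
            min(L, int(mean + 4 * sd)),
        )
        starts = (rng.random(n_frag) * (L - flens + 1)).astype(np.int64)
        carrier_draws = rng.random((n_frag, len(snvs))) if snvs else None
        err_draws = None
        for k in range(n_frag):
            frag_id += 1
            s, flen = int(starts[k]), int(flens[k])
            qname = f"f{sample_name}.{stream}.{frag_id}"
            spans = [(s, s + rl, "+"), (s + flen - rl, s + flen, "-")]
            mates = []
            for a, b, sdr in spans:
                read_slice = seq[a:b]
                if snvs:
                    for si, (dpos, alt, dosage) in enumerate(snvs):
                        if a <= dpos < b and carrier_draws[k, si] < dosage:
                            i = dpos - a
                            read_slice = read_slice[:i] + alt + read_slice[i + 1 :]
                primary, supp = _alignments_for_read(
                    deriv, offsets, a, b, sdr, cfg.min_anchor
                )
                mates.append((read_slice, sdr, primary, supp))

            p1, p2 = mates[0][2], mates[1][2]
            same_chrom = p1["chrom"] == p2["chrom"]
            lo = min(p1["pos"], p2["pos"])
            hi = max(p1["pos"] + p1["plen"], p2["pos"] + p2["plen"])
            proper = (
                same_chrom
                and p1["strand"] != p2["strand"]
                and not mates[0][3]
                and not mates[1][3]
                and (hi - lo) <= max_insert
            )
            for mi, (read_slice, sdr, primary, supp) in enumerate(mates):
                other = mates[1 - mi][2]
                read_seq = read_slice if sdr == "+" else revcomp(read_slice)
                if out_fastq_prefix is not None:
                    (fastq1 if mi == 0 else fastq2).append(
                        f"@{qname}\n{read_seq}\n+\n{'I' * rl}\n"
                    )
                flag = 1 | (64 if mi == 0 else 128)
                if proper:
                    flag |= 2
                if primary["strand"] == "-":
                    flag |= 16
                if other["strand"] == "-":
                    flag |= 32
                rnext = "=" if other["chrom"] == primary["chrom"] else other["chrom"]
                if same_chrom:
                    tlen = hi - lo
                    if primary["pos"] > other["pos"] or (
                        primary["pos"] == other["pos"] and mi == 1
                    ):
                        tlen = -tlen
                else:
                    tlen = 0
                all_alns = [primary] + supp
                for ai, aln in enumerate(all_alns):
                    others = [x for x in all_alns if x is not aln]
                    sa = "".join(
                        f"{x['chrom']},{x['pos'] + 1},{x['strand']},{_cigar(x, rl)},60,0;"
                        for x in others
                    )
                    f = flag | (2048 if ai > 0 else 0)
                    fields = [
                        qname,
                        str(f),
                        aln["chrom"],
                        str(aln["pos"] + 1),
                        "60",
                        _cigar(aln, rl),
                        rnext,
                        str(other["pos"] + 1),
                        str(tlen),
                        read_seq if aln["strand"] == "+" else revcomp(read_seq),
                        "I" * rl,
                    ]
                    if sa:
                        fields.append(f"SA:Z:{sa}")
                    records.append(
                        (order[aln["chrom"]], aln["pos"], "\t".join(fields) + "\n")
                    )

    records.sort(key=lambda t: (t[0], t[1]))
    out_sam = Path(out_sam)
    with open(out_sam, "w") as fh:
        fh.write(_sam_header(contigs))
        fh.writelines(line for _, _, line in records)
    if out_fastq_prefix is not None:
        Path(f"{out_fastq_prefix}_R1.fastq").write_text("".join(fastq1))
        Path(f"{out_fastq_prefix}_R2.fastq").write_text("".join(fastq2))
    return out_sam


# ---------------------------------------------------------------------------
# RNA read simulation


def exon_chain_on_derivative(
    reference: SyntheticReference,
    derivative: DerivativeChromosome,
    exon_labels: Sequence[str],
    allow_truncation: bool = False,
) -> List[Tuple[int, int]]:
    """Derivative-coordinate exon intervals for a transcript, in splicing order.

    For each exon the earliest complete forward-oriented derivative copy that
    keeps the chain strictly increasing is chosen; failure means the chain
    does not exist on this assembly.  With ``allow_truncation`` the chain is
    cut at the first unplaceable exon instead (reads from the missing tail
    simply do not map to this assembly).
    """
    chain: List[Tuple[int, int]] = []
    prev_end = 0
    for label in exon_labels:
        iv = reference.exon(label)
        candidates = []
        off = 0
        for piece in derivative.pieces:
            if (
                isinstance(piece, Segment)
                and piece.chrom == iv.chrom
                and piece.orientation is Orientation.FORWARD
                and piece.start <= iv.start
                and iv.end <= piece.end
            ):
                d0 = off + (iv.start - piece.start)
                candidates.append((d0, d0 + iv.length()))
            off += piece.length()
        candidates = [c for c in candidates if c[0] >= prev_end]
        if not candidates:
            if allow_truncation and chain:
                return chain
            raise ConfigurationError(
                f"exon {label!r} has no usable copy on derivative {derivative.name!r} "
                f"after offset {prev_end} (transcript not encodable on this genome)"
            )
        chosen = min(candidates)
        chain.append(chosen)
        prev_end = chosen[1]
    return chain


def _mrna_to_derivative(chain: Sequence[Tuple[int, int]], m0: int, m1: int):
    """Map mRNA interval [m0, m1) to derivative blocks via the exon chain."""
    blocks = []
    cum = 0
    for d0, d1 in chain:
        ln = d1 - d0
        lo, hi = max(m0, cum), min(m1, cum + ln)
        if lo < hi:
            blocks.append((d0 + (lo - cum), d0 + (hi - cum)))
        cum += ln
    return blocks


def _spliced_cigar(blocks: Sequence[Tuple[int, int]]) -> str:
    parts = []
    for (a0, a1), nxt in zip(blocks, list(blocks[1:]) + [None]):
        parts.append(f"{a1 - a0}M")
        if nxt is not None:
            parts.append(f"{nxt[0] - a1}N")
    return "".join(parts)


def simulate_rna_reads(
    truth: SyntheticTruth,
    sample_name: str,
    derivative: DerivativeChromosome,
    out_sam,
    n_pairs: Optional[int] = None,
    stream: int = 0,
) -> Path:
    """Emit spliced paired-end alignments on ``derivative`` for one sample.

    Reads are drawn from the sample's expressed transcripts with counts
    proportional to expression weights; splice gaps fall exactly at
    transcript exon boundaries on the derivative.
    """
    cfg = truth.config
    ref = truth.reference
    sample = truth.sample(sample_name)
    if not sample.transcripts:
        raise ConfigurationError(f"sample {sample_name!r} has no expressed transcripts")
    rl = cfg.read_len_rna
    total = n_pairs if n_pairs is not None else cfg.rna_read_pairs
    rng = np.random.default_rng(
        [cfg.seed % (2**31), 202, stream, zlib.crc32(sample_name.encode()) % (2**31)]
    )

    # every transcript must exist in full on at least one clone genome of the
    # sample; the mapping assembly may then truncate it (unmappable tail)
    clone_derivs = [
        truth.clone_derivative(sample_name, i) for i in range(len(sample.clones))
    ]
    for t in sample.transcripts:
        for cd in clone_derivs:
            try:
                exon_chain_on_derivative(ref, cd, t.exons)
                break
            except ConfigurationError:
                continue
        else:
            raise ConfigurationError(
                f"transcript {t.name!r} is not encodable on any clone genome of "
                f"sample {sample_name!r}"
            )

    dseq = derivative.assemble(ref.sequences)
    chains = [
        exon_chain_on_derivative(ref, derivative, t.exons, allow_truncation=True)
        for t in sample.transcripts
    ]
    for t, chain in zip(sample.transcripts, chains):
        if sum(d1 - d0 for d0, d1 in chain) < rl:
            raise ConfigurationError(f"transcript {t.name!r} shorter than a read")
    weights = np.array([t.weight for t in sample.transcripts], dtype=float)
    counts = rng.multinomial(total, weights / weights.sum())

    records: List[Tuple[int, str]] = []
    frag_id = 0
    for t, chain, n in zip(sample.transcripts, chains, counts):
        M = sum(d1 - d0 for d0, d1 in chain)
        if n == 0:
            continue
        flens = np.clip(
            np.rint(rng.normal(cfg.rna_insert_mean, cfg.rna_insert_sd, n)).astype(np.int64),
            rl,
            M,
        )
        starts = (rng.random(n) * (M - flens + 1)).astype(np.int64)
        for k in range(int(n)):
            frag_id += 1
            s, flen = int(starts[k]), int(flens[k])
            qname = f"r{sample_name}.{stream}.{frag_id}"
            mate_spans = [(s, s + rl, "+"), (s + flen - rl, s + flen, "-")]
            infos = []
            for m0, m1, sdr in mate_spans:
                blocks = _mrna_to_derivative(chain, m0, m1)
                seq = "".join(dseq[a:b] for a, b in blocks)
                infos.append((blocks, seq, sdr))
            pos1 = infos[0][0][0][0]
            pos2 = infos[1][0][0][0]
            end1 = infos[0][0][-1][1]
            end2 = infos[1][0][-1][1]
            tl = max(end1, end2) - min(pos1, pos2)
            for mi, (blocks, seq, sdr) in enumerate(infos):
                other_pos = pos2 if mi == 0 else pos1
                flag = 1 | 2 | (64 if mi == 0 else 128)
                if sdr == "-":
                    flag |= 16
                else:
                    flag |= 32
                # SEQ is stored on the reference (derivative) strand; the
                # flag records the sequencing orientation of the mate
                stored = seq
                my_pos = blocks[0][0]
                tlen = tl if my_pos <= other_pos else -tl
                fields = [
                    qname,
                    str(flag),
                    derivative.name,
                    str(my_pos + 1),
                    "60",
                    _spliced_cigar(blocks),
                    "=",
                    str(other_pos + 1),
                    str(tlen),
                    stored,
                    "I" * rl,
                ]
                records.append((my_pos, "\t".join(fields) + "\n"))

    records.sort(key=lambda t: t[0])
    out_sam = Path(out_sam)
    with open(out_sam, "w") as fh:
        fh.write(_sam_header({derivative.name: len(dseq)}))
        fh.writelines(line for _, line in records)
    return out_sam


# ---------------------------------------------------------------------------
# caller-style call sets


def _jitter_junction(
    j: BreakFusionJunction, rng: np.random.Generator, jitter_bp: int
) -> BreakFusionJunction:
    if jitter_bp == 0:
        return j
    dl, dr = rng.integers(-jitter_bp, jitter_bp + 1, 2)
    return BreakFusionJunction(
        Breakend(j.left.chrom, max(0, j.left.pos + int(dl)), j.left.orient),
        Breakend(j.right.chrom, max(0, j.right.pos + int(dr)), j.right.orient),
        inserted_seq=j.inserted_seq,
    )


def emit_caller_callsets(
    truth: SyntheticTruth,
    sample_name: str,
    jitter_bp: int = 150,
    fn_rate: float = 0.0,
    fp_count: int = 0,
    callers: Tuple[str, str] = ("lumpy", "delly"),
    stream: int = 0,
) -> Tuple[List[SvCall], List[SvCall]]:
    """Two caller-style call sets for one sample.

    The first caller reports split-read-precise coordinates (no jitter,
    ``precise=True``); the second caller's breakends are jittered uniformly
    within +/- ``jitter_bp``.  Each truth junction enters each call set with
    probability 1 - ``fn_rate``; ``fp_count`` caller-unique decoy deletions
    (far from every truth breakend and from each other) are appended per set.
    """
    ref = truth.reference
    rng = np.random.default_rng(
        [truth.config.seed % (2**31), 303, stream, zlib.crc32(sample_name.encode()) % (2**31)]
    )
    junctions = truth.sample_junctions(sample_name)
    gene = truth.reference.gene_body
    truth_pos = [be.pos for j in junctions for be in (j.left, j.right)]

    out: List[List[SvCall]] = [[], []]
    for ci, caller in enumerate(callers):
        jit = 0 if ci == 0 else jitter_bp
        for j in junctions:
            if rng.random() < fn_rate:
                continue
            jj = _jitter_junction(j, rng, jit)
            out[ci].append(SvCall(caller, jj, qual=60.0, precise=(ci == 0)))
        placed: List[int] = []
        n_placed = 0
        attempts = 0
        while n_placed < fp_count and attempts < 10_000:
            attempts += 1
            p = int(rng.integers(gene.start, gene.end - 6000))
            q = p + int(rng.integers(2000, 5000))
            # decoys stay >1 kb from every truth breakend and from the other
            # caller's decoys, so they can never satisfy the consensus rule
            if any(abs(p - t) < 1500 or abs(q - t) < 1500 for t in truth_pos + placed):
                continue
            placed.extend([p, q])
            n_placed += 1
            decoy = BreakFusionJunction(
                Breakend(gene.chrom, p), Breakend(gene.chrom, q)
            )
            out[ci].append(SvCall(caller, decoy, qual=10.0, precise=False))
        # decoys from the second caller must not collide with the first's
        truth_pos = truth_pos + placed
    return out[0], out[1]


# ---------------------------------------------------------------------------
# the default cohort: the study conditions in miniature


def default_cohort(
    seed: int,
    locus_len: int = 200_000,
    upstream_len: int = 60_000,
    partner_chrom_len: int = 60_000,
    coverage: float = 200.0,
    rna_read_pairs: int = 30000,
) -> SyntheticTruth:
    """Reference + samples emulating the study's informative tumour archetypes.

    Samples:

    * ``REF`` — copy-neutral, event-free (plays the copy-number reference).
    * ``S-DUP`` / ``S-DUP-CTRL`` — a tandem duplication placing the upstream
      cryptic exons downstream of exon 3 (sub-clonal fraction 0.6), driving
      three duplication-dependent variant transcripts; matched control.
    * ``S-TRA`` / ``S-TRA-CTRL`` — a translocation (with a TTTAG insertion)
      recruiting a partner-chromosome 3'-terminal exon (fraction 0.5).
    * ``S-CPX`` — a duplication plus two overlapping deletions on one allele
      (fraction 0.8), the multi-step single-allele architecture.
    * ``S-AMP`` — locus copy number 3 with an inversion (fraction 0.4) and a
      hotspot missense SNV at truth VAF 0.4.
    """
    ref = make_reference(
        seed,
        locus_len=locus_len,
        partner_chrom_len=partner_chrom_len,
        upstream_len=upstream_len,
    )
    cfg = SimConfig(seed=seed, coverage=coverage, rna_read_pairs=rna_read_pairs)

    e = {lbl: ref.exon(lbl) for lbl in ref.exon_labels()}
    gene = ref.gene_body

    # duplication: intron-3 breakpoint joined back to a point upstream of the
    # cryptic exons, so the duplicated copy carries 4-ups/5a/5b/5c
    dup_left = (e["CE3"].end + e["exon4"].start) // 2
    dup_right = round(0.20 * upstream_len)
    dup = BreakFusionJunction(
        Breakend("chrA", dup_left), Breakend("chrA", dup_right)
    )

    # translocation: intron-3 breakpoint fused (with TTTAG) to chrB upstream
    # of the partner exon
    tra_left = (e["exon3"].end + e["CE3"].start) // 2
    tra_right = max(0, e["chr11x"].start - 2000)
    tra = BreakFusionJunction(
        Breakend("chrA", tra_left), Breakend("chrB", tra_right), inserted_seq="TTTAG"
    )

    # complex allele: duplication spanning exons 5-6, two overlapping
    # deletions resolvable only on the duplicated architecture
    a1 = e["exon4"].end + 100
    qd = a1 + 4800
    a2 = qd + 500
    b1 = a2 + 2300
    pd = b1 + 500
    b2 = pd + 550
    cpx_dup = BreakFusionJunction(Breakend("chrA", pd), Breakend("chrA", qd))
    cpx_del1 = BreakFusionJunction(Breakend("chrA", a1), Breakend("chrA", b1))
    cpx_del2 = BreakFusionJunction(Breakend("chrA", a2), Breakend("chrA", b2))

    # inversion within intron 1
    inv_left = e["exon1"].end + 3000
    inv = BreakFusionJunction(
        Breakend("chrA", inv_left),
        Breakend("chrA", inv_left + 9000, Orientation.REVERSE),
    )

    # hotspot missense SNV inside the last exon's coding region
    snv_pos = e[f"exon{ref.n_exons}"].start + 90
    snv_ref = ref.sequences["chrA"][snv_pos]
    snv_alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[snv_ref]

    canonical = TranscriptSpec("AR-FL", ref.canonical_chain(), weight=8.0)
    v_dup = [
        TranscriptSpec("AR-V-5a", ("exon1", "exon2", "exon3", "4-ups", "5a-ups"), 3.0),
        TranscriptSpec("AR-V-5b", ("exon1", "exon2", "exon3", "4-ups", "5b-ups"), 2.0),
        TranscriptSpec("AR-V-5c", ("exon1", "exon2", "exon3", "4-ups", "5c-ups"), 1.0),
    ]
    v_tra = [TranscriptSpec("AR-V-chr11", ("exon1", "exon2", "exon3", "chr11x"), 3.0)]

    samples = [
        SampleSpec("REF", [CloneSpec(1.0)], [canonical]),
        SampleSpec(
            "S-DUP",
            [CloneSpec(0.6, [dup]), CloneSpec(0.4)],
            [canonical] + v_dup,
        ),
        SampleSpec("S-DUP-CTRL", [CloneSpec(1.0)], [canonical]),
        SampleSpec(
            "S-TRA",
            [CloneSpec(0.5, [tra]), CloneSpec(0.5)],
            [canonical] + v_tra,
        ),
        SampleSpec("S-TRA-CTRL", [CloneSpec(1.0)], [canonical]),
        SampleSpec(
            "S-CPX",
            [CloneSpec(0.8, [cpx_dup, cpx_del1, cpx_del2]), CloneSpec(0.2)],
            [canonical],
        ),
        SampleSpec(
            "S-AMP",
            [
                CloneSpec(0.4, [inv], locus_copy_number=3, snvs=[(snv_pos, snv_ref, snv_alt, 1.0)]),
                CloneSpec(0.6, locus_copy_number=3),
            ],
            [canonical],
        ),
    ]
    return SyntheticTruth(cfg, ref, samples)
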