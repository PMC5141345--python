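"""Transcript assembly, translation and truncated-receptor feature annotation."""

import numpy as np
import pytest

from argsr.errors import CycleError, InputError
from argsr.splicing import Bin, BinSet, JunctionCall
from argsr.derivative import DerivativeChromosome, Segment
from argsr.transcripts import (
    ProteinProduct,
    assemble_transcripts,
    molecular_weight,
    scan_nls_like,
    translate_orf,
    TranscriptModel,
)

WATER = 18.02


# ---------------------------------------------------------------------------
# assembly on the shared cohort


def test_duplication_case_assembles_canonical_plus_three_variants(splice_dup, cohort):
    models = splice_dup.models
    names = sorted(m.name for m in models)
    terminals = sorted(m.exon_labels()[-1] for m in models)
    assert len(models) == 4
    assert terminals == ["5a-ups.2", "5b-ups.2", "5c-ups.2", "exon8"]
    variants = [m for m in models if m.exon_labels()[-1] != "exon8"]
    for m in variants:
        assert m.exon_labels()[:4] == ["exon1", "exon2", "exon3", "4-ups.2"]


def test_translocation_case_recruits_partner_terminal_exon(splice_tra):
    models = splice_tra.models
    assert len(models) == 1
    assert models[0].exon_labels() == ["exon1", "exon2", "exon3", "chr11x"]


def test_rna_round_trip_reproduces_generator_proteins(splice_dup, splice_tra, cohort):
    """Full pipeline (simulate -> junctions -> assembly -> translation)
    reproduces the generator's mRNA and protein sequences exactly, including
    extension lengths and NLS-like flags."""
    ref = cohort.reference
    expected = {
        "exon8": ref.canonical_chain(),
        "5a-ups.2": ("exon1", "exon2", "exon3", "4-ups", "5a-ups"),
        "5b-ups.2": ("exon1", "exon2", "exon3", "4-ups", "5b-ups"),
        "5c-ups.2": ("exon1", "exon2", "exon3", "4-ups", "5c-ups"),
        "chr11x": ("exon1", "exon2", "exon3", "chr11x"),
    }
    expected_ext = {"5a-ups.2": 15, "5b-ups.2": 18, "5c-ups.2": 13, "chr11x": 13, "exon8": 0}
    canonical_protein = ref.protein(ref.canonical_chain())
    for res in (splice_dup, splice_tra):
        for model in res.models:
            terminal = model.exon_labels()[-1]
            chain = expected[terminal]
            assert model.mrna == ref.mrna(chain)
            product = res.products[model.name]
            assert product.sequence == ref.protein(chain)
            assert len(product.cterm_extension) == expected_ext[terminal]
            if terminal == "exon8":
                assert product.sequence == canonical_protein
                assert not product.nls_like
            else:
                assert product.nls_like
    dup_motifs = {
        p.nls_motif for n, p in splice_dup.products.items() if p.cterm_extension
    }
    assert dup_motifs == {"VRRGR"}
    (tra_product,) = [p for p in splice_tra.products.values()]
    assert tra_product.nls_motif == "VGKTK"
    assert tra_product.cterm_extension == "VGKTKSGVEDNLL"


def test_variant_molecular_weights_are_v7_like(splice_dup, cohort):
    """Truncated variants lacking the ligand-binding domain cluster well
    below the canonical receptor's weight, like the reference variant class."""
    canonical = [p for p in splice_dup.products.values() if not p.cterm_extension]
    variants = [p for p in splice_dup.products.values() if p.cterm_extension]
    assert canonical and variants
    for v in variants:
        assert v.mol_weight < 0.75 * canonical[0].mol_weight
    spread = max(v.mol_weight for v in variants) - min(v.mol_weight for v in variants)
    assert spread < 1_000  # daltons; co-migrating on a blot


# ---------------------------------------------------------------------------
# translation


_CODON_TABLE = {}


def _oracle_translate(cds):
    """Independent codon-table translation used as the oracle."""
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        for i, b1 in enumerate(bases):
            for j, b2 in enumerate(bases):
                for k, b3 in enumerate(bases):
                    _CODON_TABLE[b1 + b2 + b3] = aas[16 * i + 4 * j + k]
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def _model(mrna):
    return TranscriptModel("t", [("e", 0, len(mrna))], mrna)


def test_translation_agrees_with_codon_table_oracle():
    rng = np.random.default_rng(8)
    for _ in range(300):
        n = int(rng.integers(6, 120))
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        mrna = "ATG" + body
        protein, stopped = _oracle_translate(mrna)
        product = translate_orf(_model(mrna), 0)
        assert product.sequence == protein
        assert product.non_stop == (not stopped)


def test_minimal_orf():
    product = translate_orf(_model("ATGTAA"), 0)
    assert product.sequence == "M"
    assert not product.non_stop


def test_start_codon_required():
    with pytest.raises(InputError):
        translate_orf(_model("TTGAAATAA"), 0)


def test_canonical_prefix_and_extension():
    canonical = "MKLV"
    # MKLV then extension "RW"
    mrna = "ATGAAACTGGTGCGTTGGTAA"
    product = translate_orf(_model(mrna), 0, canonical_protein=canonical)
    assert product.canonical_prefix_len == 4
    assert product.cterm_extension == "RW"


def test_frame_carried_across_splice_junctions(cohort):
    """A variant mRNA's extension is read in the frame set by the canonical
    exons, so the translated extension starts exactly at the junction codon."""
    ref = cohort.reference
    chain = ("exon1", "exon2", "exon3", "4-ups", "5a-ups")
    mrna = ref.mrna(chain)
    product = translate_orf(
        TranscriptModel("v", [("x", 0, len(mrna))], mrna),
        ref.start_codon_offset,
        canonical_protein=ref.protein(ref.canonical_chain()),
    )
    assert product.cterm_extension.startswith("VRRGR")


# ---------------------------------------------------------------------------
# NLS scan and molecular weight


@pytest.mark.parametrize(
    "extension,flag,motif",
    [
        ("VRRGRAQHLS", True, "VRRGR"),
        ("VGKTKSGVEDNLL", True, "VGKTK"),
        ("AAAAAAA", False, ""),
        ("", False, ""),
    ],
)
def test_nls_like_scan(extension, flag, motif):
    p = ProteinProduct("X" * 10 + extension, 10, extension, 0.0)
    got_flag, got_motif = scan_nls_like(p)
    assert got_flag == flag and got_motif == motif


def test_nls_scan_ignores_residues_outside_window():
    ext = "A" * 15 + "KRKRK"
    p = ProteinProduct("M" + ext, 1, ext, 0.0)
    assert scan_nls_like(p, window=15)[0] is False
    assert scan_nls_like(p, window=25)[0] is True


def test_glycine_molecular_weight():
    assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)


def test_molecular_weight_concatenation_additivity():
    a, b = "MKV", "GRW"
    assert molecular_weight(a + b) == pytest.approx(
        molecular_weight(a) + molecular_weight(b) - WATER, abs=0.02
    )


def test_empty_sequence_weight_is_an_error():
    with pytest.raises(InputError):
        molecular_weight("")


# ---------------------------------------------------------------------------
# junction-graph edge cases


def test_cyclic_junction_graph_raises():
    bins = BinSet(
        [
            Bin("exon1", 0, 100, "exon"),
            Bin("intron.1", 100, 200, "intron"),
            Bin("exon2", 200, 300, "exon"),
        ]
    )
    deriv = DerivativeChromosome("der", [Segment("chr1", 0, 300)])
    ref = {"chr1": "A" * 300}
    calls = [
        JunctionCall(100, 200, 10, 0, False, "canonical"),
        JunctionCall(300, 0, 5, 0, False, "novel"),  # exon2 back to exon1
    ]
    with pytest.raises(CycleError):
        assemble_transcripts(calls, bins, deriv, ref, start_exon="exon1")


def test_unknown_start_exon_raises():
    bins = BinSet([Bin("exon1", 0, 100, "exon")])
    deriv = DerivativeChromosome("der", [Segment("chr1", 0, 100)])
    with pytest.raises(InputError):
        assemble_transcripts([], bins, deriv, {"chr1": "A" * 100}, start_exon="exon9")


def test_unannotated_acceptor_opens_terminal_exon():
    bins = BinSet(
        [
            Bin("exon1", 0, 100, "exon"),
            Bin("intron.1", 100, 1_000, "intron"),
        ]
    )
    deriv = DerivativeChromosome("der", [Segment("chr1", 0, 1_000)])
    ref = {"chr1": "A" * 1_000}
    calls = [JunctionCall(100, 400, 10, 0, False, "rearrangement_dependent")]
    (model,) = assemble_transcripts(
        calls, bins, deriv, ref, start_exon="exon1", terminal_extension=300
    )
    assert model.exons[-1] == ("novel@400", 400, 700)
    assert len(model.mrna) == 400
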