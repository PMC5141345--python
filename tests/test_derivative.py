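"""Derivative construction, liftover and single-allele reconstruction."""

import itertools

import numpy as np
import pytest

from argsr.derivative import (
    DerivativeChromosome,
    Segment,
    build_derivative,
    combined_reference,
    reconstruct_allele,
)
from argsr.errors import JunctionApplicationError
from argsr.genome import (
    Breakend,
    BreakFusionJunction,
    GenomicInterval,
    Orientation,
    parse_breakend_notation,
    revcomp,
)

from table1 import C6_JUNCTIONS, C12A_DUPLICATION, C12A_DUPLICATION_KB


def _rand_ref(seed, lengths):
    rng = np.random.default_rng(seed)
    return {
        name: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        for name, n in lengths.items()
    }


def test_published_duplication_size_rounds_to_379_kb():
    """Coordinate-only construction on hg19 positions: the tandem duplication
    adds a segment whose size matches the published 379 kb figure."""
    dup = parse_breakend_notation(C12A_DUPLICATION)
    win = GenomicInterval("chrX", 66_000_000, 67_500_000)
    deriv = build_derivative(None, [dup], win)
    added = len(deriv) - win.length()
    assert round(added / 1000) == C12A_DUPLICATION_KB


def test_empty_junction_list_is_identity():
    win = GenomicInterval("chr1", 100, 600)
    d = build_derivative(None, [], win)
    assert len(d) == 500
    assert d.lift(0) == ("chr1", 100, Orientation.FORWARD)
    assert d.lift_back("chr1", 599) == [(499, Orientation.FORWARD)]


def test_translocation_seam_sequence():
    ref = _rand_ref(3, {"chr1": 2000, "chr2": 2000})
    j = BreakFusionJunction(
        Breakend("chr1", 700), Breakend("chr2", 300), inserted_seq="TTTAG"
    )
    wins = {
        "chr1": GenomicInterval("chr1", 0, 2000),
        "chr2": GenomicInterval("chr2", 0, 2000),
    }
    d = build_derivative(ref, [j], wins)
    seq = d.assemble(ref)
    seam = ref["chr1"][695:701] + "TTTAG" + ref["chr2"][300:306]
    assert seam in seq
    assert len(d) == 701 + 5 + 1700


def test_deletion_duplication_inversion_sequences():
    ref = _rand_ref(4, {"chr1": 3000})
    win = GenomicInterval("chr1", 0, 3000)
    s = ref["chr1"]

    dele = BreakFusionJunction(Breakend("chr1", 999), Breakend("chr1", 2000))
    assert build_derivative(ref, [dele], win).assemble(ref) == s[:1000] + s[2000:]

    dup = BreakFusionJunction(Breakend("chr1", 1999), Breakend("chr1", 1000))
    assert (
        build_derivative(ref, [dup], win).assemble(ref)
        == s[:2000] + s[1000:2000] + s[2000:]
    )

    inv = BreakFusionJunction(
        Breakend("chr1", 999), Breakend("chr1", 2000, Orientation.REVERSE)
    )
    assert (
        build_derivative(ref, [inv], win).assemble(ref)
        == s[:1000] + revcomp(s[1000:2001]) + s[2001:]
    )

    inv2 = BreakFusionJunction(
        Breakend("chr1", 1000, Orientation.REVERSE), Breakend("chr1", 2001)
    )
    assert (
        build_derivative(ref, [inv2], win).assemble(ref)
        == s[:1000] + revcomp(s[1000:2001]) + s[2001:]
    )


def test_lift_round_trip_on_random_probes():
    win = GenomicInterval("chr1", 0, 3000)
    dup = BreakFusionJunction(Breakend("chr1", 1999), Breakend("chr1", 1000))
    dele = BreakFusionJunction(Breakend("chr1", 2399), Breakend("chr1", 2600))
    d = build_derivative(None, [dup, dele], win)
    rng = np.random.default_rng(0)
    for pos in rng.integers(0, len(d), 1000):
        chrom, src, orient = d.lift(int(pos))
        assert chrom == "chr1"
        back = d.lift_back(chrom, src)
        assert (int(pos), orient) in back
        for bpos, borient in back:
            assert d.lift(bpos) == (chrom, src, borient)


def test_lift_back_inside_duplication_returns_two_copies():
    win = GenomicInterval("chr1", 0, 3000)
    dup = BreakFusionJunction(Breakend("chr1", 1999), Breakend("chr1", 1000))
    d = build_derivative(None, [dup], win)
    assert len(d.lift_back("chr1", 1500)) == 2
    assert len(d.lift_back("chr1", 500)) == 1


def test_interval_straddling_deletion_seam_splits_with_gap():
    win = GenomicInterval("chr1", 0, 3000)
    dele = BreakFusionJunction(Breakend("chr1", 999), Breakend("chr1", 2000))
    d = build_derivative(None, [dele], win)
    parts = d.lift_interval(900, 1100)
    assert len(parts) == 2
    (iv1, _), (iv2, _) = parts
    assert iv1.end == 1000 and iv2.start == 2000
    assert iv2.start - iv1.end == 1000  # the deleted length
    assert iv1.length() + iv2.length() == 200


def test_length_conservation_for_random_nonoverlapping_events():
    rng = np.random.default_rng(7)
    win = GenomicInterval("chr1", 0, 50_000)
    for _ in range(25):
        cursor, juncs, delta = 1000, [], 0
        while cursor < 40_000 and len(juncs) < 4:
            a = cursor + int(rng.integers(200, 1500))
            b = a + int(rng.integers(300, 3000))
            kind = rng.integers(0, 2)
            if kind == 0:
                juncs.append(BreakFusionJunction(Breakend("chr1", a), Breakend("chr1", b)))
                delta -= b - a - 1
            else:
                juncs.append(BreakFusionJunction(Breakend("chr1", b), Breakend("chr1", a)))
                delta += b - a + 1
            cursor = b + 500
        d = build_derivative(None, juncs, win)
        assert len(d) == win.length() + delta


def test_overlapping_deletion_application_is_an_error():
    win = GenomicInterval("chr1", 0, 10_000)
    d1 = BreakFusionJunction(Breakend("chr1", 1000), Breakend("chr1", 5000))
    d2 = BreakFusionJunction(Breakend("chr1", 2000), Breakend("chr1", 3000))
    with pytest.raises(JunctionApplicationError):
        build_derivative(None, [d1, d2], win)


def test_masking_in_combined_reference():
    ref = _rand_ref(9, {"chr1": 1000, "chr2": 500})
    win = GenomicInterval("chr1", 100, 900)
    dele = BreakFusionJunction(Breakend("chr1", 399), Breakend("chr1", 600))
    d = build_derivative(ref, [dele], {"chr1": win}, name="der1")
    combined = combined_reference(ref, d)
    assert combined["chr1"][100:900] == "N" * 800
    assert combined["chr1"][:100] == ref["chr1"][:100]
    assert combined["der1"] == d.assemble(ref)
    assert combined["chr2"] == ref["chr2"]


# ---------------------------------------------------------------------------
# allele reconstruction


def test_published_c6_architecture_reconstructs_with_duplication_first():
    """The three C-6 junctions co-exist on one allele only if the tandem
    duplication happened before the two deletions."""
    juncs = [parse_breakend_notation(t) for t in C6_JUNCTIONS]
    rec = reconstruct_allele(
        juncs, None, GenomicInterval("chrX", 66_900_000, 66_950_461)
    )
    assert rec.consistent
    assert rec.operation_order[0].svclass == "duplication"
    assert {j.svclass for j in rec.operation_order[1:]} == {"deletion"}
    for j in juncs:
        assert rec.derivative.contains_junction(j)
    # the three deletions cannot coexist on an unduplicated linear allele:
    # deletion 1 and deletion 2 overlap on the reference
    d1, _, d2 = juncs
    assert d1.right.pos > d2.left.pos


def test_single_deletion_reconstructs_trivially():
    j = BreakFusionJunction(Breakend("chr1", 1000), Breakend("chr1", 2000))
    rec = reconstruct_allele([j], None, GenomicInterval("chr1", 0, 5000))
    assert rec.consistent and rec.operation_order == [j]


def test_mutually_erasing_deletions_are_inconsistent():
    """A deletion that removes the other deletion's junction (engineered on a
    toy genome) cannot co-exist with it; exhaustive order enumeration agrees."""
    win = GenomicInterval("chr1", 0, 10_000)
    inner = BreakFusionJunction(Breakend("chr1", 3000), Breakend("chr1", 4000))
    outer = BreakFusionJunction(Breakend("chr1", 2000), Breakend("chr1", 5000))

    def order_oracle():
        for order in itertools.permutations([inner, outer]):
            try:
                d = build_derivative(None, list(order), win)
            except JunctionApplicationError:
                continue
            if all(d.contains_junction(j) for j in (inner, outer)):
                return True
        return False

    assert order_oracle() is False
    rec = reconstruct_allele([inner, outer], None, win)
    assert rec.consistent is False
    assert rec.derivative is None


def test_reconstruction_matches_order_oracle_on_random_pairs():
    rng = np.random.default_rng(13)
    win = GenomicInterval("chr1", 0, 30_000)
    for _ in range(20):
        pts = sorted(rng.choice(np.arange(1000, 29_000), size=4, replace=False))
        a, b, c, d = (int(x) for x in pts)
        j1 = BreakFusionJunction(Breakend("chr1", a), Breakend("chr1", b))
        j2 = BreakFusionJunction(Breakend("chr1", c), Breakend("chr1", d))
        if rng.random() < 0.5:
            j2 = BreakFusionJunction(Breakend("chr1", d), Breakend("chr1", c))

        expected = False
        for order in itertools.permutations([j1, j2]):
            try:
                deriv = build_derivative(None, list(order), win)
            except JunctionApplicationError:
                continue
            if all(deriv.contains_junction(j) for j in (j1, j2)):
                expected = True
                break
        rec = reconstruct_allele([j1, j2], None, win)
        assert rec.consistent == expected
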