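"""Synthetic cohort generator: determinism, geometry and statistical structure."""

import numpy as np
import pysam
import pytest

from argsr.errors import ConfigurationError
from argsr.genome import Breakend, BreakFusionJunction, GenomicInterval
from argsr.simulate import (
    CloneSpec,
    SampleSpec,
    SimConfig,
    SyntheticTruth,
    TranscriptSpec,
    emit_caller_callsets,
    make_reference,
    simulate_dna_reads,
    simulate_rna_reads,
)

SMALL = dict(locus_len=50_000, upstream_len=50_000, partner_chrom_len=30_000)


def test_reference_is_deterministic_in_seed(tmp_path):
    a = make_reference(3, **SMALL)
    b = make_reference(3, **SMALL)
    c = make_reference(4, **SMALL)
    assert a.sequences == b.sequences
    assert a.exons == b.exons
    assert a.sequences != c.sequences


def test_reference_layout():
    ref = make_reference(3, **SMALL)
    labels = ref.exon_labels()
    assert sum(lbl.startswith("exon") for lbl in labels) == 8
    for cryptic in ("CE3", "4-ups", "5a-ups", "5b-ups", "5c-ups", "chr11x"):
        assert cryptic in labels
    assert ref.gene_body.length() == 50_000
    assert len(ref.sequences["chrB"]) == 30_000
    assert len(ref.control_regions) == 5
    # the CDS through exon 3 keeps phase 0 so variant extensions read in frame
    coding = sum(ref.exon(f"exon{i}").length() for i in (2, 3))
    assert coding % 3 == 0


def test_infeasible_layouts_rejected():
    with pytest.raises(ConfigurationError):
        make_reference(1, locus_len=10_000)
    with pytest.raises(ConfigurationError):
        make_reference(1, locus_len=50_000, upstream_len=5_000)


def _single_sample_truth(ref, clones, seed=9, coverage=60.0, transcripts=()):
    return SyntheticTruth(
        SimConfig(seed=seed, coverage=coverage),
        ref,
        [SampleSpec("S", clones, list(transcripts))],
    )


def test_clone_fractions_must_sum_to_one():
    with pytest.raises(ConfigurationError):
        SampleSpec("bad", [CloneSpec(0.5), CloneSpec(0.4)])


def test_dna_simulation_deterministic(small_ref, tmp_path):
    truth = _single_sample_truth(small_ref, [CloneSpec(1.0)], coverage=10)
    p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
    simulate_dna_reads(truth, "S", p1, out_fastq_prefix=str(tmp_path / "a"))
    simulate_dna_reads(truth, "S", p2, out_fastq_prefix=str(tmp_path / "b"))
    assert p1.read_bytes() == p2.read_bytes()
    assert (tmp_path / "a_R1.fastq").read_bytes() == (tmp_path / "b_R1.fastq").read_bytes()


def test_event_free_sample_has_no_junction_evidence(small_ref, tmp_path):
    truth = _single_sample_truth(small_ref, [CloneSpec(1.0)], coverage=30)
    sam = tmp_path / "flat.sam"
    simulate_dna_reads(truth, "S", sam)
    n = 0
    with pysam.AlignmentFile(str(sam)) as fh:
        for rec in fh:
            n += 1
            assert not rec.has_tag("SA")
            assert not rec.is_supplementary
            assert rec.is_proper_pair
    assert n > 1000


def test_coverage_conservation_within_two_percent(small_ref, tmp_path):
    """A copy-number-2 genome receives the configured fold coverage overall."""
    truth = _single_sample_truth(
        small_ref, [CloneSpec(1.0, locus_copy_number=2)], coverage=50
    )
    sam = tmp_path / "cov.sam"
    simulate_dna_reads(truth, "S", sam)
    total = 0
    with pysam.AlignmentFile(str(sam)) as fh:
        for rec in fh:
            if not rec.is_supplementary:
                total += rec.query_length
    genome = sum(len(s) for s in small_ref.sequences.values())
    assert abs(total / (50 * genome) - 1) < 0.02


def test_junction_read_support_matches_geometric_expectation(small_ref, tmp_path):
    """Split-read count at a clonal deletion junction is within 3 s.d. of the
    closed-form expectation from read length, anchor length and depth."""
    g = small_ref.gene_body
    dele = BreakFusionJunction(
        Breakend("chrA", g.start + 15_000), Breakend("chrA", g.start + 25_000)
    )
    cov = 100.0
    truth = _single_sample_truth(small_ref, [CloneSpec(1.0, [dele])], coverage=cov)
    sam = tmp_path / "del.sam"
    simulate_dna_reads(truth, "S", sam)
    from argsr.detect import scan_junction_evidence

    ev = scan_junction_evidence(sam, dele)
    cfg = truth.config
    rl, anchor = cfg.read_len_dna, cfg.min_anchor
    depth = cov / 2.0  # single-copy locus
    expect_sr = depth * (rl - 2 * anchor + 1) / rl
    sd = np.sqrt(expect_sr)
    assert abs(ev.sr_support - expect_sr) <= 3 * sd


def test_snv_dosage_in_reads(small_ref, tmp_path):
    pos = small_ref.exon("exon8").start + 50
    ref_base = small_ref.sequences["chrA"][pos]
    alt = "A" if ref_base != "A" else "G"
    truth = _single_sample_truth(
        small_ref,
        [CloneSpec(1.0, snvs=[(pos, ref_base, alt, 0.4)])],
        coverage=120,
    )
    sam = tmp_path / "snv.sam"
    simulate_dna_reads(truth, "S", sam)
    from argsr.snv import pileup_counts

    counts = pileup_counts(sam, GenomicInterval("chrA", pos, pos + 1))
    column = counts[pos]
    depth = sum(column.values())
    vaf = column[alt] / depth
    assert abs(vaf - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / depth)


# ---------------------------------------------------------------------------
# RNA simulation


def test_single_exon_transcript_has_no_spliced_junctions(small_ref, tmp_path):
    truth = _single_sample_truth(
        small_ref,
        [CloneSpec(1.0)],
        transcripts=[TranscriptSpec("one", ("exon1",), 1.0)],
    )
    truth.config.rna_read_pairs = 500
    deriv = truth.mapping_derivative("S")
    sam = tmp_path / "rna1.sam"
    simulate_rna_reads(truth, "S", deriv, sam)
    from argsr.splicing import extract_junctions

    junctions, retained, _ = extract_junctions(sam)
    assert junctions == {} and retained == 0


def test_junction_counts_follow_expression_weights(small_ref, tmp_path):
    """Two transcripts at 9:1 weight produce junction counts within binomial
    error of 9:1 (distinct terminal exons disambiguate the junctions)."""
    t_major = TranscriptSpec("major", ("exon1", "exon2"), 9.0)
    t_minor = TranscriptSpec("minor", ("exon1", "exon3"), 1.0)
    truth = _single_sample_truth(
        small_ref, [CloneSpec(1.0)], transcripts=[t_major, t_minor]
    )
    truth.config.rna_read_pairs = 8000
    deriv = truth.mapping_derivative("S")
    sam = tmp_path / "rna9.sam"
    simulate_rna_reads(truth, "S", deriv, sam)
    from argsr.splicing import extract_junctions

    junctions, _, _ = extract_junctions(sam)
    e1_end = small_ref.exon("exon1").end
    major = sum(c for (d, a), c in junctions.items() if a == small_ref.exon("exon2").start)
    minor = sum(c for (d, a), c in junctions.items() if a == small_ref.exon("exon3").start)
    n = major + minor
    p_hat = major / n
    assert abs(p_hat - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / n)
    assert all(d == e1_end for d, _ in junctions)


def test_transcript_not_on_any_clone_genome_is_an_error(small_ref, tmp_path):
    variant = TranscriptSpec("v", ("exon1", "exon2", "exon3", "4-ups"), 1.0)
    truth = _single_sample_truth(small_ref, [CloneSpec(1.0)], transcripts=[variant])
    deriv = truth.mapping_derivative("S")
    with pytest.raises(ConfigurationError):
        simulate_rna_reads(truth, "S", deriv, tmp_path / "bad.sam")


def test_rearrangement_dependent_junctions_absent_without_the_clone(cohort, tmp_path):
    """The control sample, mapped to the case's derivative, never shows the
    variant splice junction into the duplicated upstream exons."""
    from argsr.simulate import exon_chain_on_derivative
    from argsr.splicing import extract_junctions

    deriv = cohort.mapping_derivative("S-DUP")
    sam = tmp_path / "ctrl.sam"
    simulate_rna_reads(cohort, "S-DUP-CTRL", deriv, sam)
    junctions, _, _ = extract_junctions(sam)
    chain = exon_chain_on_derivative(
        cohort.reference, deriv, ("exon1", "exon2", "exon3", "4-ups")
    )
    variant_junction = (chain[2][1], chain[3][0])  # exon3 end -> 4-ups copy 2
    assert variant_junction not in junctions
    assert junctions  # canonical splicing is still observed


# ---------------------------------------------------------------------------
# caller call sets


def test_exact_callsets_reproduce_truth(cohort):
    calls_a, calls_b = emit_caller_callsets(
        cohort, "S-CPX", jitter_bp=0, fn_rate=0.0, fp_count=0
    )
    truth_j = cohort.sample_junctions("S-CPX")
    for calls in (calls_a, calls_b):
        assert [(c.junction.left, c.junction.right) for c in calls] == [
            (j.left, j.right) for j in truth_j
        ]
    assert all(c.precise for c in calls_a)


def test_decoys_are_caller_unique_and_counted(cohort):
    calls_a, calls_b = emit_caller_callsets(
        cohort, "S-DUP", jitter_bp=0, fn_rate=0.0, fp_count=5
    )
    truth_n = len(cohort.sample_junctions("S-DUP"))
    assert len(calls_a) == truth_n + 5
    assert len(calls_b) == truth_n + 5
    decoys_a = [c.junction for c in calls_a[truth_n:]]
    decoys_b = [c.junction for c in calls_b[truth_n:]]
    for da in decoys_a:
        for db in decoys_b:
            assert (
                abs(da.left.pos - db.left.pos) > 1000
                or abs(da.right.pos - db.right.pos) > 1000
            )


def test_truth_serialization_round_trip(cohort, tmp_path):
    path = tmp_path / "truth.json"
    cohort.to_json(path)
    back = SyntheticTruth.from_json(path)
    assert back.reference.sequences == cohort.reference.sequences
    assert [s.name for s in back.samples] == [s.name for s in cohort.samples]
    for s1, s2 in zip(back.samples, cohort.samples):
        assert [c.events for c in s1.clones] == [c.events for c in s2.clones]
        assert s1.transcripts == s2.transcripts


def test_expected_vaf_and_cn_helpers(cohort):
    j = cohort.sample_junctions("S-DUP")[0]
    assert cohort.expected_vaf("S-DUP", j) == pytest.approx(0.6)
    assert cohort.expected_cn_ratio("S-AMP", "REF") == pytest.approx(3.0)
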