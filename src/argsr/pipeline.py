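"""End-to-end orchestration of the analysis stages on a synthetic cohort.

Each function runs one sample (or one case/control pair) through the same
decision rules a real cohort would see: dual-caller consensus, support and
gene-body filtering, the cDNA-contamination rule, copy-number normalization,
VAF estimation, dual-rule-set SNV consensus, and the derivative-mapped
splice-junction analysis with transcript assembly and translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .derivative import DerivativeChromosome
from .detect import (
    GsrEvent,
    extract_support,
    filter_candidates,
    flag_cdna_contamination,
    merge_callsets,
    scan_junction_evidence,
)
from .quantify import CopyNumberProfile, VafEstimate, copy_number, estimate_vaf
from .simulate import SyntheticTruth, emit_caller_callsets, simulate_dna_reads, simulate_rna_reads
from .snv import SnvCall, call_ruleset_a, call_ruleset_b, consensus_snvs
from .splicing import (
    JunctionCall,
    SpliceJunctionMatrix,
    call_rearrangement_dependent,
    extract_junctions,
    junction_matrix,
    make_bins,
)
from .stats import cohort_summary
from .transcripts import ProteinProduct, TranscriptModel, assemble_transcripts, scan_nls_like, translate_orf

__all__ = ["SampleResult", "SpliceResult", "run_dna_sample", "run_cohort", "run_splice_analysis"]

#: pipeline-level amplification call threshold; the strict >1 definition plus
#: a noise margin for coverage sampling (the bare definition is configurable
#: in quantify.copy_number)
AMP_THRESHOLD = 1.25


@dataclass
class SampleResult:
    sample: str
    sam_path: Path
    candidates: List[GsrEvent]
    validated: List[GsrEvent]
    contaminated: bool
    cn: Optional[CopyNumberProfile]
    snvs: List[SnvCall]
    vafs: Dict[str, VafEstimate] = field(default_factory=dict)

    @property
    def gsr_positive(self) -> bool:
        return bool(self.validated) and not self.contaminated

    def summary_row(self) -> dict:
        events = []
        for ev in self.validated:
            ev.vaf = self.vafs[str(ev.junction)].vaf if str(ev.junction) in self.vafs else None
            events.append(ev)
        return dict(
            sample=self.sample,
            amplified=self.cn.amplified if self.cn else False,
            cn_ratio=self.cn.cn_ratio_vs_reference if self.cn else float("nan"),
            snvs=[f"{c.chrom}:{c.pos + 1}{c.ref}>{c.alt}" for c in self.snvs],
            events=events,
            contaminated=self.contaminated,
        )


def run_dna_sample(
    truth: SyntheticTruth,
    sample_name: str,
    workdir,
    reference_sam,
    fp_count: int = 5,
    jitter_bp: int = 150,
    fn_rate: float = 0.0,
    sam_path: Optional[Path] = None,
) -> SampleResult:
    """Simulate (if needed) and analyse one sample's DNA evidence."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref = truth.reference
    cfg = truth.config
    if sam_path is None:
        sam_path = workdir / f"{sample_name}.dna.sam"
        simulate_dna_reads(truth, sample_name, sam_path)

    calls_a, calls_b = emit_caller_callsets(
        truth, sample_name, jitter_bp=jitter_bp, fn_rate=fn_rate, fp_count=fp_count
    )
    candidates = merge_callsets(calls_a, calls_b, sample=sample_name)
    scan_kw = dict(insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd)
    for ev in candidates:
        ev.pe_support, ev.sr_support = extract_support(ev.junction, sam_path, **scan_kw)
    validated = filter_candidates(candidates, ref.gene_body)
    contaminated, _ = flag_cdna_contamination(validated, ref.exons)

    cn = copy_number(
        sam_path,
        ref.gene_body,
        ref.control_regions,
        reference_sam,
        sample=sample_name,
        amp_threshold=AMP_THRESHOLD,
    )

    snvs_a = call_ruleset_a(sam_path, ref.gene_body, ref.sequences)
    snvs_b = call_ruleset_b(sam_path, ref.gene_body, ref.sequences)
    snvs = consensus_snvs(snvs_a, snvs_b)

    vafs = {str(ev.junction): estimate_vaf(ev, sam_path, **scan_kw) for ev in validated}
    return SampleResult(
        sample=sample_name,
        sam_path=sam_path,
        candidates=candidates,
        validated=validated,
        contaminated=contaminated,
        cn=cn,
        snvs=snvs,
        vafs=vafs,
    )


def run_cohort(
    truth: SyntheticTruth,
    workdir,
    sample_names: Optional[Sequence[str]] = None,
    reference_sample: str = "REF",
    fp_count: int = 5,
    jitter_bp: int = 150,
):
    """Run the DNA pipeline over a cohort and build the oncoprint-style summary.

    Returns ``(results by sample, summary DataFrame, contingency tables)``.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    names = list(sample_names) if sample_names else [s.name for s in truth.samples]
    ref_sam = workdir / f"{reference_sample}.dna.sam"
    if not ref_sam.exists():
        simulate_dna_reads(truth, reference_sample, ref_sam)
    results = {}
    for name in names:
        sam = workdir / f"{name}.dna.sam"
        if name == reference_sample:
            sam = ref_sam
        elif not sam.exists():
            sam = None
        results[name] = run_dna_sample(
            truth,
            name,
            workdir,
            ref_sam,
            fp_count=fp_count,
            jitter_bp=jitter_bp,
            sam_path=sam,
        )
    table, tables = cohort_summary([r.summary_row() for r in results.values()])
    return results, table, tables


@dataclass
class SpliceResult:
    derivative: DerivativeChromosome
    matrix_case: SpliceJunctionMatrix
    matrix_control: SpliceJunctionMatrix
    calls: List[JunctionCall]
    models: List[TranscriptModel]
    products: Dict[str, ProteinProduct]


def run_splice_analysis(
    truth: SyntheticTruth,
    case: str,
    control: str,
    workdir,
    min_reads: int = 3,
) -> SpliceResult:
    """Map case and control RNA onto the case's derivative and call tumour-specific splicing.

    Transcript models are assembled from the canonical plus
    rearrangement-dependent junctions, translated from the receptor start
    codon and annotated for NLS-like C-terminal motifs.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref = truth.reference
    derivative = truth.mapping_derivative(case)

    sam_case = workdir / f"{case}.rna.sam"
    sam_ctrl = workdir / f"{control}.rna.sam"
    simulate_rna_reads(truth, case, derivative, sam_case)
    simulate_rna_reads(truth, control, derivative, sam_ctrl)

    jx_case, ret_c, disc_c = extract_junctions(sam_case)
    jx_ctrl, ret_k, disc_k = extract_junctions(sam_ctrl)
    bins = make_bins(derivative, ref.exons)
    m_case = junction_matrix(jx_case, bins, ret_c, disc_c)
    m_ctrl = junction_matrix(jx_ctrl, bins, ret_k, disc_k)
    calls = call_rearrangement_dependent(jx_case, jx_ctrl, derivative, bins, min_reads)

    usable = [c for c in calls if c.status in ("canonical", "rearrangement_dependent")]
    models = assemble_transcripts(
        usable, bins, derivative, ref.sequences, start_exon="exon1", sample=case
    )
    canonical_protein = ref.protein(ref.canonical_chain())
    products = {}
    for model in models:
        product = translate_orf(model, ref.start_codon_offset, canonical_protein)
        scan_nls_like(product)
        products[model.name] = product
    return SpliceResult(
        derivative=derivative,
        matrix_case=m_case,
        matrix_control=m_ctrl,
        calls=calls,
        models=models,
        products=products,
    )
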