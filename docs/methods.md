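# Methods

`argsr` re-implements, as a tested library, an integrative targeted-sequencing
analysis of structural rearrangements of the androgen receptor (*AR*) locus in
prostate cancer: consensus detection of break-fusion junctions from paired-end
capture DNA-seq, copy-number and sub-clonal allele-fraction quantification,
reconstruction of the rearranged (derivative) gene architecture, and discovery
of rearrangement-dependent truncated-receptor (AR-V) transcripts from RNA-seq
splice junctions mapped to that architecture. Because the original patient
reads are controlled-access, a first-class synthetic cohort generator supplies
data with the statistical structure the analysis assumes; every pipeline stage
is validated against the generator's ground truth.

## Coordinates and breakend semantics

Internally all coordinates are 0-based, half-open; anything printed or parsed
(region strings, breakend notation, VCF/SAM) is 1-based inclusive. A
break-fusion junction (BFJ) is two oriented breakends plus an optional
non-templated insertion. On the left breakend, `(+)` means the derivative
retains reference sequence approaching the position from below; on the right
breakend, `(+)` means it continues from the position upward (reverse flips
the respective direction). Under this convention the four rearrangement
classes are purely geometric: different chromosomes → translocation; exactly
one reverse orientation → inversion; both forward with left < right →
deletion; both forward with left > right → tandem duplication. Two identical
forward breakends are rejected as degenerate. A printed row that omits an
orientation token is parsed as forward with a warning (the one such published
row is a duplication, consistent with forward/forward).

Junction signatures are annotated as non-homologous end-joining evidence:
the non-templated length is the insertion length, and microhomology is the
span over which the breakpoint placement is ambiguous (shifting the junction
within that span reproduces the identical derivative sequence), reported
left-aligned. A junction with an insertion has zero microhomology by
construction, so the two quantities are never both positive.

## Derivative chromosomes, liftover and allele reconstruction

A derivative chromosome is an ordered walk of oriented reference segments
with insertions at seams. Junctions are applied *in order* to the evolving
walk — a deletion removes the bases strictly between its breakends, a tandem
duplication inserts a second copy of the bracketed derivative stretch, an
inversion reverse-complements the bracketed stretch, and a translocation
replaces the tail with the partner-chromosome window. Adjacent
source-contiguous segments are coalesced, so seams are exactly the
non-contiguous adjacencies; this makes the seam list, the liftover map and
simulated read clipping mutually consistent. Lifting is bidirectional:
derivative → source is total on non-inserted bases, source → derivative
returns every copy (two or more inside duplications), and intervals are split
at seams. Applying a junction whose breakend was removed by a prior event is
an error rather than a silent repair.

`reconstruct_allele` answers whether several junctions can co-exist on one
DNA molecule: it searches operation orders (duplications before deletions,
then by coordinate, the preferred order first) and, within an order, every
breakend placement among duplicated copies, accepting a reconstruction only
if every input junction signature appears among the final walk's seams.
Inconsistency is a result, not an error. On the published three-junction
case this recovers the duplication-first model; with at most 5 junctions the
search space (≤ 5! orders × a handful of placements) is trivially small.

For read mapping the package emits a combined reference in which every source
window contributing a segment is hard-masked (N-filled) and the derivative is
added as an extra contig, forcing reads from the rearranged allele onto it.

## Synthetic cohort generator

The generator is the package's model of the study conditions, not a fixture:

* **Reference.** Chromosome A carries an AR-like gene (default 200 kb, 8
  exons) with 60 kb upstream and 20 kb downstream flanks; cryptic exons are a
  CE3-like exon in intron 3 and four upstream exons (`4-ups`, `5a/5b/5c-ups`).
  Chromosome B (default 60 kb) carries the translocation-partner exon and the
  five copy-number control regions, placed below any recruited tail so a
  translocation never perturbs control coverage. Coding structure is designed
  so that every canonical splice phase is 0: variant transcripts that splice
  exon 3 onto a cryptic exon read the designed C-terminal extension in frame.
  `4-ups` contributes an open VRRGR-initiated cassette; `5a/5b/5c-ups`, CE3
  and the partner exon terminate translation, giving extensions of 15, 18,
  13, 16 and 13 residues respectively.
* **Clones.** A sample is a mixture of clones (fractions summing to 1), each
  with an ordered junction list, an integer locus copy number and hotspot
  SNVs with per-copy dosage.
* **DNA reads.** 2×150 bp pairs with insert length ~ Normal(300, 50)
  truncated at ±4 s.d. (so event-free fragments are always concordant), drawn
  per clone molecule with expected depth `coverage × copy_number / 2`
  (controls sit at copy number 2, the locus at the clone's state — 1 is the
  X-chromosome baseline). Reads are placed on the clone's derivative and
  lifted back to reference coordinates; pieces of at least 20 bp (the
  `min_anchor` an aligner would place) become primary/supplementary split
  alignments with SA tags, shorter overhangs become soft-clips. Sequencing
  error is off by default and base qualities are constant: no stage consumes
  them, and error modelling would only blur the decision rules under test.
* **RNA reads.** 2×50 bp stranded pairs drawn from the sample's expressed
  transcripts with counts proportional to expression weights, emitted as
  spliced alignments (N-gaps exactly at exon boundaries) on a chosen mapping
  assembly. Each transcript must exist in full on at least one clone genome;
  on the mapping assembly it may be truncated (reads from a missing tail
  simply do not map, as with a real truncating translocation).
* **Call sets.** Two caller-style call sets: the first reports split-read
  precise coordinates, the second is jittered uniformly within ±150 bp
  (well inside the 1 kb merge rule); false negatives are Bernoulli per call
  and decoy deletions are caller-unique by construction (>1 kb from every
  truth breakend and from the other caller's decoys).

Every output is a pure function of (configuration, seed); RNG streams are
derived from the seed and a CRC of the sample name.

What the generator does **not** emulate: alignment ambiguity in repeats (the
real locus is LINE/SINE-rich and ~15% unmappable), capture-efficiency and GC
bias, sequencing error, PCR duplicates, and reciprocal translocation
partners. Passing tests therefore demonstrate the correctness of the decision
rules on structurally faithful evidence, not robustness to mapping artefacts.

## Detection, quantification and SNV rules

Consensus merging requires the same chromosome pair and class with *both*
breakend distances ≤ 1000 bp (inclusive — the stricter reading of "within
1 kb"); matching is one-to-one, greedy by summed distance with ties broken by
lower coordinate, and consensus coordinates come from a split-read-precise
call when flagged, else from the first call set. Validation requires at least
one breakend in the gene body (default `chrX:66763873-66950461`) and ≥10
discordant pairs and ≥10 split reads, counted from mapq ≥ 20, non-duplicate
records; split reads need alignment edges at both breakends within ±10 bp,
and pairs whose split mate's primary flanks the junction also count as
discordant pairs (fragments are deduplicated by name wherever pairs must be
counted once). A sample whose validated candidates are all deletions
coinciding (±5 bp) with annotated splice donor/acceptor sites is flagged as
cDNA-contaminated and reported rearrangement-negative.

Copy number is `meanCov(locus) / mean(meanCov(C1..C5))`, per-region means,
ratioed against a copy-neutral reference sample; the amplification call is
strict `> 1` at the operation level, while the pipeline applies a 1.25
threshold as a noise margin for coverage sampling. VAF is fragment-level:
junction-supporting fragments over supporting plus the mean count of
concordant fragments spanning each breakend with ≥20 bp margin, with a
Clopper–Pearson 95% interval. On single-copy deletion junctions the
estimator's absolute bias is below 0.05 at 200× junction depth (the
acceptance suite measures it); at duplication and translocation junctions the
*measured* VAF is intrinsically diluted relative to the clone fraction — the
duplicated allele retains intact copies of both breakend positions, and a
translocation partner contributes its own normal copies — which is a property
of fragment-counting VAF itself, not an estimator defect.

SNV calling is deliberately reduced to the two published threshold rule sets
on pileup counts (rule set A: ≥3 variant reads, ≥10% fraction, depth ≥20;
rule set B: mapq ≥5 pileup, ≥1% fraction), with the consensus keyed on
(chrom, pos, ref, alt) and VAF reported from rule set A; genotype-likelihood
machinery is out of scope because only the thresholded intersection feeds the
analysis. Multi-allelic sites emit one record per alternate allele.

## Splice matrices and transcript assembly

Splice junctions are extracted from gapped alignments, keeping a gap only if
the read aligns ≥5 bp on each side (inclusive). Exon/intron bins tile the
derivative (duplicated exon copies get `.2` suffixes) and junction counts
fill the ordered (donor bin, acceptor bin) matrix — the heatmap. Against a
matched control mapped to the same assembly, a case junction is
*rearrangement-dependent* if the control lacks it and it either crosses a
rearrangement seam or reaches `min_reads` (default 3, a documented choice —
no published threshold exists); control-shared junctions at annotated
boundaries are canonical. Note that on a duplication assembly the canonical
exon3→exon4 junction legitimately crosses the seams (the duplicated copy
sits inside the enlarged intron), which is exactly why the matched-control
rule, not seam-crossing alone, decides tumour specificity.

Transcripts are assembled by walking the junction graph from exon 1, taking
branches in order of decreasing read count (ties by lower acceptor
coordinate) and emitting one model per 3′-terminal branch; an acceptor
without an annotated exon opens a terminal exon of 300 bp (coverage-extent
support is accepted when supplied). Translation runs from the receptor start
codon to the first in-frame stop (run-off products are returned flagged);
the C-terminal extension is everything beyond the longest common prefix with
the canonical translation. The NLS-like scan looks in the first 15 extension
residues for a 5-residue window with at least 2 basic residues (K/R) — the
threshold that flags the VRRGR, VGKTK, ARKLK and EKFRM motif family while
leaving non-basic extensions unflagged. Molecular weight uses average (not
monoisotopic) residue masses, matching gel-mobility comparisons.

## Statistics

The two-tailed Fisher exact test sums the point probabilities of all tables
with the observed margins that do not exceed the observed table's; point
probabilities are compared as exact integer weights, so no floating-point
tolerance enters the tail definition. This convention reproduces the three
published cohort p-values (0.0450, 0.0741, 0.0021) to four decimals, and the
test suite verifies exact agreement with an exhaustive enumeration oracle on
every table with n ≤ 40. One-sided Mann–Whitney U uses exact enumeration for
small untied samples and the tie-corrected normal approximation otherwise
(normality pre-testing is not implemented — it only motivates the choice of
a rank test). Relative expression uses the differential-Ct transform
`2^-(ΔCt_sample − ΔCt_calibrator)` with the calibrator fixed at 1. No
multiple-testing correction is applied, matching the analysis reproduced.

## Problem sizes and numerical choices

The cohort used by the test suite and the acceptance script scales the gene
to 80 kb (50 kb upstream, 40 kb partner chromosome) at 120× configured
coverage with 12 000 RNA pairs per sample — sizes chosen so junction support
comfortably exceeds the ≥10/≥10 thresholds while a full cohort analysis
stays in the minutes range; the VAF-bias study uses a 50 kb gene at 400×
configured coverage (200× on the single-copy locus) with 4 replicates per
truth fraction. All decision rules are size-independent. Degenerate inputs
fail loudly: zero-coverage controls, zero-depth VAF, unsorted alignment
streams, infeasible exon layouts, cyclic junction graphs and inapplicable
junctions each raise a dedicated exception.

## Known limitations

* Inversions are applied to forward-oriented derivative stretches; nested or
  double inversions are out of scope, as are multi-breakend (>2) records.
* Translocations are modelled as non-reciprocal (the derivative keeps one
  product), so gene-body coverage genuinely drops beyond a truncating
  breakpoint — copy-number truth comparisons are made on copy-uniform
  samples.
* The fragment-level VAF dilution at duplication/translocation junctions
  described above is reported as measured, not corrected.
* The cDNA-contamination rule follows the all-candidates-splice-coincident
  definition; a sample mixing genuine and contamination-derived junctions is
  (correctly, per the rule) not flagged.
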