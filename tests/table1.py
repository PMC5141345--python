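"""The published break-fusion-junction table: notation, class and VAF per row."""

# (patient, tumour, printed junction notation, rearrangement class, VAF % or None)
TABLE1_ROWS = [
    ("C-4", "A", "chrX:66,804,042 (+)/chrX:66,816,507 (+)", "deletion", 7.32),
    ("C-4", "A", "chrX:66,754,961 (+)/chrX:66,843,254 (+)", "deletion", 7.88),
    ("C-6", "A", "chrX:66,934,778 (+)/chrX:66,942,396 (+)", "deletion", 46.99),
    ("C-6", "A", "chrX:66,942,924 (+)/chrX:66,939,551 (+)", "duplication", 74.15),
    ("C-6", "A", "chrX:66,940,040 (+)/chrX:66,943,474 (+)", "deletion", 42.68),
    ("C-6", "B", "chrX:66,934,778 (+)/chrX:66,942,396 (+)", "deletion", 43.45),
    ("C-6", "B", "chrX:66,942,924 (+)/chrX:66,939,551 (+)", "duplication", 49.19),
    ("C-6", "B", "chrX:66,940,040 (+)/chrX:66,943,474 (+)", "deletion", 38.23),
    ("C-7", "A", "chrX:49,150,734 (+)/chrX:66,779,010 (+)", "deletion", 4.26),
    ("C-7", "B", "chrX:49,150,734 (+)/chrX:66,779,010 (+)", "deletion", 5.40),
    ("C-9", "A", "chrX:66,909,163 (+)/TTTAG/chr11:79,397,735 (+)", "translocation", 13.74),
    ("C-12", "A", "chrX:66,786,453 (+)/chrX:66,862,260 (+)", "deletion", 13.13),
    ("C-12", "A", "chrX:66,765,788 (+)/chrX:66,738,768 (+)", "duplication", 4.71),
    ("C-12", "A", "chrX:66,909,930 (+)/chrX:66,530,990 (+)", "duplication", 33.25),
    ("C-12", "B", "chrX:66,786,453 (+)/chrX:66,862,260 (+)", "deletion", 46.28),
    ("C-12", "B", "chrX:66,765,788 (+)/chrX:66,738,768 (+)", "duplication", 25.87),
    ("C-12", "B", "chrX:66,767,448 (+)/chrX:66,026,083 (+)", "duplication", 5.66),
    ("C-14", "A", "chrX:65,828,372 (−)/chrX:66,816,576 (+)", "inversion", 4.52),
    ("C-14", "A", "chrX:66,919,966 (+)/chrX:67,012,163 (−)", "inversion", 1.62),
    ("C-14", "B", "chrX:66,908,944 (−)/66,922,090 (+)", "inversion", 1.86),
    ("C-14", "B", "chrX:66,929,712 (+)/chrX:66,921,594", "duplication", 2.65),
    ("P-1", "TURP", "chrX:66,935,187 (+)/chrX:66,938,063 (−)", "inversion", None),
    ("P-14", "TURP", "chrX:67,337,657 (+)/chrX:66,909,110 (+)", "duplication", 2.19),
]

#: the three printed cohort contingency tables and their two-tailed Fisher p-values
FISHER_TABLES = {
    "gsr_vs_amplification": ((7, 5, 3, 15), 0.0450),
    "gsr_vs_mutation": ((0, 6, 10, 14), 0.0741),
    "crpc_restriction": ((12, 24, 0, 21), 0.0021),
}

#: C-6's three junctions (one tumour) and the published multi-step model
C6_JUNCTIONS = [
    "chrX:66,934,778 (+)/chrX:66,942,396 (+)",  # deletion 1
    "chrX:66,942,924 (+)/chrX:66,939,551 (+)",  # duplication
    "chrX:66,940,040 (+)/chrX:66,943,474 (+)",  # deletion 2
]

#: the C-12A tandem duplication and its published size (nearest kb)
C12A_DUPLICATION = "chrX:66,909,930 (+)/chrX:66,530,990 (+)"
C12A_DUPLICATION_KB = 379
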