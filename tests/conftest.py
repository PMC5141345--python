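"""Shared fixtures: a small deterministic reference and one analysed cohort.

The heavy pieces (read simulation and the full DNA pipeline) are session
fixtures computed once and shared between the unit tests and the acceptance
suite.  Problem sizes are scaled down from the defaults (80 kb gene instead
of 200 kb, 120x configured coverage) — the decision rules under test are
size-independent.
"""

from __future__ import annotations

import warnings

import pytest

from argsr.pipeline import run_cohort, run_splice_analysis
from argsr.simulate import default_cohort, make_reference

# the C-14B duplication row legitimately lacks an orientation token; silence
# the parser's warning for the whole suite
warnings.filterwarnings("ignore", message="orientation token missing")

COHORT_SEED = 5
COHORT_KW = dict(
    locus_len=80_000,
    upstream_len=50_000,
    partner_chrom_len=40_000,
    coverage=120.0,
    rna_read_pairs=12_000,
)


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(11, locus_len=50_000, upstream_len=50_000, partner_chrom_len=30_000)


@pytest.fixture(scope="session")
def cohort():
    return default_cohort(COHORT_SEED, **COHORT_KW)


@pytest.fixture(scope="session")
def cohort_run(cohort, tmp_path_factory):
    """(truth, per-sample results, summary table, contingency tables, workdir)."""
    workdir = tmp_path_factory.mktemp("cohort")
    results, table, tables = run_cohort(cohort, workdir)
    return cohort, results, table, tables, workdir


@pytest.fixture(scope="session")
def splice_dup(cohort, tmp_path_factory):
    return run_splice_analysis(cohort, "S-DUP", "S-DUP-CTRL", tmp_path_factory.mktemp("rna_dup"))


@pytest.fixture(scope="session")
def splice_tra(cohort, tmp_path_factory):
    return run_splice_analysis(cohort, "S-TRA", "S-TRA-CTRL", tmp_path_factory.mktemp("rna_tra"))
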