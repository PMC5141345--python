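"""Cohort statistics: exact Fisher test, one-sided Mann-Whitney U, ddCt transform.

The two-tailed Fisher test follows the "sum of point probabilities no larger
than the observed table's" convention, computed in exact rational arithmetic
so that no floating-point tolerance enters the tail definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "ContingencyTable2x2",
    "ExpressionRecord",
    "fisher_exact_two_tailed",
    "mann_whitney_one_sided",
    "ddct_relative_expression",
    "cohort_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise InputError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p: sum of point probabilities <= the observed one.

    All tables with the observed margins are enumerated; each table's
    hypergeometric point probability is proportional to the integer weight
    C(r1, k) * C(r2, c1 - k), so the tail condition is evaluated by exact
    integer comparison and no floating-point tolerance enters the test.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return float(Fraction(num, sum(weights)))


def mann_whitney_one_sided(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "y_greater",
) -> Tuple[float, float]:
    """One-sided Mann-Whitney U test; returns (U statistic for x, p-value).

    ``alternative`` is ``"x_greater"`` or ``"y_greater"``.  The p-value is
    exact (full enumeration of the U null distribution) for small untied
    samples and a tie-corrected normal approximation otherwise, matching
    standard practice.
    """
    if alternative not in ("x_greater", "y_greater"):
        raise InputError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not ties) else "asymptotic"
    scipy_alt = "greater" if alternative == "x_greater" else "less"
    res = sps.mannwhitneyu(x, y, alternative=scipy_alt, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ExpressionRecord:
    """qRT-PCR measurement for one sample: target and housekeeping Ct values."""

    sample: str
    target_ct: float
    housekeeping_ct: float
    relative_expression: Optional[float] = None

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.housekeeping_ct


def ddct_relative_expression(
    records: Sequence[ExpressionRecord], calibrator: str
) -> List[ExpressionRecord]:
    """Differential-Ct transform: fold expression relative to a calibrator sample.

    relative = 2^-((Ct_target - Ct_housekeeping)_sample - (dCt)_calibrator);
    the calibrator's own relative expression is exactly 1.
    """
    by_name = {r.sample: r for r in records}
    if calibrator not in by_name:
        raise InputError(f"calibrator sample {calibrator!r} not among records")
    cal_dct = by_name[calibrator].delta_ct
    return [
        replace(r, relative_expression=2.0 ** (-(r.delta_ct - cal_dct)))
        for r in records
    ]


def cohort_summary(samples: Iterable[dict]):
    """Oncoprint-style per-sample table plus the cohort 2x2 association tables.

    Each element of ``samples`` is a mapping with keys ``sample``,
    ``amplified``, ``cn_ratio``, ``snvs`` (list of labels), ``events`` (list
    of validated GSR events), ``contaminated`` (bool).  A sample flagged as
    cDNA-contaminated is reported GSR-negative regardless of its candidates.

    Returns ``(table, tables)`` where ``tables`` maps a comparison name to a
    :class:`ContingencyTable2x2` (GSR vs amplification, GSR vs mutation).
    """
    import pandas as pd

    rows = []
    for s in samples:
        events = [] if s.get("contaminated") else list(s.get("events", []))
        classes = sorted({e.junction.svclass for e in events}) if events else []
        vafs = [getattr(e, "vaf", None) for e in events]
        vafs = [v for v in vafs if v is not None]
        rows.append(
            dict(
                sample=s["sample"],
                amplified=bool(s.get("amplified", False)),
                cn_ratio=s.get("cn_ratio", float("nan")),
                n_snvs=len(s.get("snvs", [])),
                snvs=";".join(map(str, s.get("snvs", []))) or ".",
                gsr_positive=len(events) > 0,
                n_gsr=len(events),
                gsr_classes=";".join(classes) or ".",
                contaminated=bool(s.get("contaminated", False)),
                max_gsr_vaf=max(vafs) if vafs else float("nan"),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample",
            "amplified",
            "cn_ratio",
            "n_snvs",
            "snvs",
            "gsr_positive",
            "n_gsr",
            "gsr_classes",
            "contaminated",
            "max_gsr_vaf",
        ],
    )
    tables = {}
    if len(table):
        amp, gsr = table["amplified"], table["gsr_positive"]
        mut = table["n_snvs"] > 0
        tables["gsr_vs_amplification"] = ContingencyTable2x2(
            int((amp & gsr).sum()),
            int((amp & ~gsr).sum()),
            int((~amp & gsr).sum()),
            int((~amp & ~gsr).sum()),
        )
        tables["gsr_vs_mutation"] = ContingencyTable2x2(
            int((mut & gsr).sum()),
            int((mut & ~gsr).sum()),
            int((~mut & gsr).sum()),
            int((~mut & ~gsr).sum()),
        )
    return table, tables
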