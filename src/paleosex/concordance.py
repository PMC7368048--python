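"""Cross-method agreement, read-depth stratification and preservation stats.

Conventions (documented because they drive the headline counts):

* Pairwise denominators include only samples where BOTH methods give a
  non-indeterminate call.
* A conflicting pair is "definitive" only when both estimates are
  definitive; if at least one side is conditional-tier (genomic conditional,
  osteological probable/possible) the conflict is "conditional".
* Read-depth comparisons are strict: "above threshold" means reads > t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Certainty, CohortTable, Method, SampleRecord, Sex, SexEstimate

__all__ = [
    "PairwiseAgreement",
    "StratifiedConflictReport",
    "sensitivity_summary",
    "pairwise_agreement",
    "stratified_conflicts",
    "reads_threshold_census",
    "log_group_compare",
    "log_regression",
]


@dataclass(frozen=True)
class PairwiseAgreement:
    method_a: Method
    method_b: Method
    n_both_called: int
    n_agree: int
    n_conflict_definitive: int
    n_conflict_conditional: int
    agree_ids: tuple[str, ...]
    conflict_definitive_ids: tuple[str, ...]
    conflict_conditional_ids: tuple[str, ...]
    n_both_definitive: int
    n_conditional_tier: int

    def __post_init__(self) -> None:
        if self.n_agree + self.n_conflict_definitive + self.n_conflict_conditional != self.n_both_called:
            raise ValueError("agreement cells must partition the denominator")

    @property
    def fraction_agree(self) -> float:
        return self.n_agree / self.n_both_called if self.n_both_called else float("nan")


@dataclass(frozen=True)
class StratifiedCell:
    n: int
    n_conflict: int
    ids: tuple[str, ...]
    conflict_ids: tuple[str, ...]


@dataclass(frozen=True)
class StratifiedConflictReport:
    genomic_method: Method
    reference_method: Method
    threshold: int
    cells: dict[tuple[str, str], StratifiedCell]  # (above|below, definitive|conditional)
    n_excluded_missing_reads: int


def _called(rec: SampleRecord, method: Method) -> SexEstimate | None:
    est = rec.estimate(method)
    return est if est is not None and est.is_called else None


def sensitivity_summary(cohort: CohortTable) -> pd.DataFrame:
    """Per-method call counts: called / definitive / conditional-tier /
    indeterminate plus the called fraction of the whole cohort."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    n = len(cohort)
    for method in Method:
        n_called = n_def = n_cond = n_indet = 0
        for rec in cohort:
            est = rec.estimate(method)
            if est is None or not est.is_called:
                n_indet += 1
                continue
            n_called += 1
            if est.is_definitive:
                n_def += 1
            else:
                n_cond += 1
        rows.append(
            {
                "method": method.value,
                "n_called": n_called,
                "n_definitive": n_def,
                "n_conditional": n_cond,
                "n_indeterminate": n_indet,
                "fraction_called": n_called / n,
            }
        )
    return pd.DataFrame(rows).set_index("method")


def pairwise_agreement(
    cohort: CohortTable, method_a: Method, method_b: Method
) -> PairwiseAgreement:
    """Agreement and tiered-conflict accounting for one method pair."""
    present = cohort.methods()
    for m in (method_a, method_b):
        if m not in present:
            raise ValueError(f"method {m.value} absent from cohort")
    agree: list[str] = []
    conflict_def: list[str] = []
    conflict_cond: list[str] = []
    n_both_def = 0
    for rec in cohort:
        est_a = _called(rec, method_a)
        est_b = _called(rec, method_b)
        if est_a is None or est_b is None:
            continue
        both_definitive = est_a.is_definitive and est_b.is_definitive
        if both_definitive:
            n_both_def += 1
        if est_a.sex is est_b.sex:
            agree.append(rec.sample_id)
        elif both_definitive:
            conflict_def.append(rec.sample_id)
        else:
            conflict_cond.append(rec.sample_id)
    n_both = len(agree) + len(conflict_def) + len(conflict_cond)
    return PairwiseAgreement(
        method_a=method_a,
        method_b=method_b,
        n_both_called=n_both,
        n_agree=len(agree),
        n_conflict_definitive=len(conflict_def),
        n_conflict_conditional=len(conflict_cond),
        agree_ids=tuple(agree),
        conflict_definitive_ids=tuple(conflict_def),
        conflict_conditional_ids=tuple(conflict_cond),
        n_both_definitive=n_both_def,
        n_conditional_tier=n_both - n_both_def,
    )


def stratified_conflicts(
    cohort: CohortTable,
    genomic_method: Method,
    reference_method: Method = Method.PROTEOMIC,
    threshold: int = 100_000,
) -> StratifiedConflictReport:
    """Split genomic-vs-reference conflicts by read depth and certainty tier.

    Cells are keyed by (stratum, tier) where stratum is "above"/"below" the
    read threshold (strict >) and tier is the GENOMIC estimate's certainty
    ("definitive"/"conditional").  Samples lacking read counts are excluded
    and tallied.
    """
    cells: dict[tuple[str, str], dict] = {
        (s, t): {"ids": [], "conflicts": []}
        for s in ("above", "below")
        for t in ("definitive", "conditional")
    }
    excluded = 0
    for rec in cohort:
        est_g = _called(rec, genomic_method)
        est_r = _called(rec, reference_method)
        if est_g is None or est_r is None:
            continue
        if rec.total_mapped_reads is None:
            excluded += 1
            continue
        stratum = "above" if rec.total_mapped_reads > threshold else "below"
        tier = "definitive" if est_g.is_definitive else "conditional"
        cell = cells[(stratum, tier)]
        cell["ids"].append(rec.sample_id)
        if est_g.sex is not est_r.sex:
            cell["conflicts"].append(rec.sample_id)
    return StratifiedConflictReport(
        genomic_method=genomic_method,
        reference_method=reference_method,
        threshold=threshold,
        cells={
            key: StratifiedCell(
                n=len(v["ids"]),
                n_conflict=len(v["conflicts"]),
                ids=tuple(v["ids"]),
                conflict_ids=tuple(v["conflicts"]),
            )
            for key, v in cells.items()
        },
        n_excluded_missing_reads=excluded,
    )


def reads_threshold_census(
    cohort: CohortTable, threshold: int = 100_000
) -> tuple[int, int, float]:
    """(n_above, n_total, fraction) with strict > comparison.

    Samples without a read count (DNA never attempted) count toward the
    denominator but never the numerator.
    """
    n_total = len(cohort)
    n_above = sum(
        1
        for rec in cohort
        if rec.total_mapped_reads is not None and rec.total_mapped_reads > threshold
    )
    return n_above, n_total, n_above / n_total if n_total else float("nan")


@dataclass(frozen=True)
class GroupCompareResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p: float
    n_a: int
    n_b: int
    n_excluded: int


def log_group_compare(
    values_a, values_b, base10: bool = True
) -> GroupCompareResult:
    """Student pooled-variance two-sample t-test on log-transformed values.

    Non-positive values are excluded before the transform (with the exclusion
    count reported); df = n_a + n_b - 2 by construction.
    """
    raw_a = np.asarray(values_a, dtype=float)
    raw_b = np.asarray(values_b, dtype=float)
    a = raw_a[raw_a > 0]
    b = raw_b[raw_b > 0]
    excluded = (len(raw_a) - len(a)) + (len(raw_b) - len(b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 positive values")
    log = np.log10 if base10 else np.log
    la, lb = log(a), log(b)
    t, p = stats.ttest_ind(la, lb, equal_var=True)
    return GroupCompareResult(
        mean_a=float(la.mean()),
        sd_a=float(la.std(ddof=1)),
        mean_b=float(lb.mean()),
        sd_b=float(lb.std(ddof=1)),
        t=float(t),
        df=len(la) + len(lb) - 2,
        p=float(p),
        n_a=len(la),
        n_b=len(lb),
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    df: int
    p_slope: float
    r: float
    n_excluded: int


def log_regression(x_values, y_values) -> RegressionResult:
    """OLS on log10-log10 scale; pairs with a non-positive member dropped."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    keep = (x > 0) & (y > 0)
    excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 usable pairs")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(ly, ly[0]):
        # constant response: slope exactly 0, no sampling variation to test
        return RegressionResult(0.0, float(ly[0]), len(x) - 2, 1.0, 0.0, excluded)
    res = stats.linregress(lx, ly)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        df=len(x) - 2,
        p_slope=float(res.pvalue),
        r=float(res.rvalue),
        n_excluded=excluded,
    )


def agreement_table(cohort: CohortTable) -> pd.DataFrame:
    """All-pairs agreement summary (one row per unordered method pair)."""
    methods = sorted(cohort.methods(), key=lambda m: m.value)
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            pw = pairwise_agreement(cohort, a, b)
            rows.append(
                {
                    "method_a": a.value,
                    "method_b": b.value,
                    "n_both_called": pw.n_both_called,
                    "n_agree": pw.n_agree,
                    "pct_agree": 100.0 * pw.fraction_agree,
                    "n_conflict_definitive": pw.n_conflict_definitive,
                    "n_both_definitive": pw.n_both_definitive,
                    "n_conflict_conditional": pw.n_conflict_conditional,
                    "n_conditional_tier": pw.n_conditional_tier,
                }
            )
    return pd.DataFrame(rows)
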