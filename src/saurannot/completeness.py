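"""Annotation completeness against conserved-gene reference sets.

Completeness is the fraction of a reference gene set (CEGMA/BUSCO-style
conserved genes, housekeeping gene panels, ...) recovered by nucleotide
search against the annotation's consensus sequences, together with the
mean aligned coverage of the recovered references (union of all passing
hit intervals on the reference).  A companion Welch two-sample t-test
compares quality statistics (e.g., lengths) of annotated sequences
against orphans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from saurannot.search import SearchParams, get_profile, search_nucleotide
from saurannot.seqio import SequenceRecord

__all__ = [
    "CompletenessReport",
    "WelchTTest",
    "assess_completeness",
    "compare_annotated_vs_orphans",
    "interval_union_length",
]


@dataclass(frozen=True)
class CompletenessReport:
    """Recovery of one reference gene set by an annotation."""

    reference_set: str
    n_reference: int
    n_found: int
    mean_coverage: float  # mean aligned reference fraction over found references
    mean_coverage_defined: bool  # False when n_found == 0 (mean reported as 0)

    @property
    def fraction_found(self) -> float:
        return self.n_found / self.n_reference


def interval_union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_lo, cur_hi = ivs[0]
    for lo, hi in ivs[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return total


def assess_completeness(
    reference_records: Sequence[SequenceRecord],
    consensus_records: Sequence[SequenceRecord],
    params: SearchParams | None = None,
    label: str = "reference",
) -> CompletenessReport:
    """Search a reference gene set against consensuses and report recovery.

    A reference counts as found when at least one hit passes the search
    thresholds (default: the stringent e-value 1e-5 nucleotide profile
    with no identity floor).  Per found reference, coverage is the union
    of ALL its passing hit intervals on the reference divided by the
    reference length; the report averages coverage over found references.
    An empty reference set is an error; an empty consensus set yields
    fraction_found 0 with the mean coverage flagged undefined.
    """
    if not reference_records:
        raise ValueError("assess_completeness requires a non-empty reference set")
    if params is None:
        params = get_profile("completeness")
    n_ref = len(reference_records)
    if not consensus_records:
        return CompletenessReport(label, n_ref, 0, 0.0, mean_coverage_defined=False)
    hits = search_nucleotide(reference_records, consensus_records, params)
    by_query: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append((h.query_start, h.query_end))
    lengths = {r.id: len(r) for r in reference_records}
    coverages = [
        interval_union_length(ivs) / lengths[qid] for qid, ivs in by_query.items()
    ]
    n_found = len(coverages)
    if n_found == 0:
        return CompletenessReport(label, n_ref, 0, 0.0, mean_coverage_defined=False)
    return CompletenessReport(
        label, n_ref, n_found, float(np.mean(coverages)), mean_coverage_defined=True
    )


@dataclass(frozen=True)
class WelchTTest:
    t: float
    df: float
    p_value: float


def compare_annotated_vs_orphans(
    values_annotated: Sequence[float], values_orphan: Sequence[float]
) -> WelchTTest:
    """Welch unequal-variance two-sample t-test (two-sided).

    Compares a quality statistic (typically sequence length or contig
    coverage) between annotated sequences and orphans.  Degrees of freedom
    follow Welch–Satterthwaite.  Requires both samples of size >= 2 with
    positive variance.
    """
    a = np.asarray(values_annotated, dtype=float)
    b = np.asarray(values_orphan, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must contain at least two observations")
    if a.var(ddof=1) <= 0 or b.var(ddof=1) <= 0:
        raise ValueError("degenerate variance: both samples must have positive variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(df):
        raise ValueError("degenerate variance: Welch degrees of freedom undefined")
    return WelchTTest(t=t, df=df, p_value=p)
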