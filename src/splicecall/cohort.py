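"""Cohort-level combination: median empirical p-value and junction calls.

Each junction's per-sample empirical p-values are reduced to their median —
the cohort score — using only samples where the junction passed all four
per-sample filters.  The median is robust to a single spuriously small
emp_p, which is exactly the multiple-testing failure mode when one junction
is tested in many samples.  Junctions whose cohort score falls strictly
below the calling threshold (default 0.15) are called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CALL_THRESHOLD = 0.15


@dataclass
class CohortJunctionRow:
    junction_key: tuple  # (chrom, intron_start, intron_end)
    strand: str
    cohort_score: float  # median emp_p over eligible samples; 1.0 if none
    n_samples_detected: int
    n_samples_eligible: int
    called: bool = False
    reason: str = ""  # "no_eligible_sample" when nothing entered the median


@dataclass
class CohortCallTable:
    rows: list  # CohortJunctionRow, sorted by junction key
    threshold: float = DEFAULT_CALL_THRESHOLD

    def as_dict(self) -> dict:
        return {r.junction_key: r for r in self.rows}


def combine_median(per_sample_scores: dict) -> CohortCallTable:
    """Median of eligible per-sample emp_p values per junction.

    ``per_sample_scores`` maps junction key -> list of JunctionSampleScore
    (one per sample where the junction was detected).  Samples where a
    junction failed any filter contribute their detection but not their
    emp_p; an even count of eligible values takes the mean of the two
    central ones.  A junction with zero eligible samples gets score 1.0 and
    a reason flag, so it can never be called.
    """
    if not per_sample_scores:
        raise ValueError("no per-sample scores to combine")
    rows = []
    for key in sorted(per_sample_scores):
        scores = per_sample_scores[key]
        eligible = [s.emp_p for s in scores if s.eligible_for_median]
        strand = next(
            (s.junction.strand for s in scores if s.junction.strand != "unknown"),
            "unknown",
        )
        if eligible:
            med = float(np.median(eligible))
            reason = ""
        else:
            med = 1.0
            reason = "no_eligible_sample"
        rows.append(
            CohortJunctionRow(
                junction_key=key,
                strand=strand,
                cohort_score=med,
                n_samples_detected=len(scores),
                n_samples_eligible=len(eligible),
                reason=reason,
            )
        )
    return CohortCallTable(rows=rows)


def call_junctions(
    table: CohortCallTable, threshold: float = DEFAULT_CALL_THRESHOLD
) -> CohortCallTable:
    """Mark junctions with cohort score strictly below the threshold."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    table.threshold = threshold
    for row in table.rows:
        row.called = row.cohort_score < threshold
    return table
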