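"""Depth QC and positivity calling against a background threshold.

A sample passes QC when its total read count reaches the minimum depth
(default 500).  A passing sample is positive when its allele fraction
strictly exceeds the background threshold at full precision.  At the
individual level, an individual is evaluable when at least one of its
(selected) samples passes QC and positive when any passing replicate is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .background import BackgroundModel, allele_fraction
from .errors import EmptySelectionError
from .tables import AmpliconSample, Cohort, CohortTable

__all__ = ["CallResult", "GroupCounts", "CohortCallSummary", "qc_pass", "call_sample", "call_cohort"]

DEFAULT_MIN_DEPTH = 500


@dataclass(frozen=True)
class CallResult:
    """Per-sample call: allele fraction, QC status, and (when QC passes)
    positivity against the threshold."""

    sample_id: str
    allele_fraction: float
    qc_pass: bool
    qc_reason: str = ""
    positive: bool | None = None

    def __post_init__(self) -> None:
        if self.positive and not self.qc_pass:
            raise ValueError("a failing-QC sample cannot be positive")


@dataclass(frozen=True)
class GroupCounts:
    evaluable: int
    positive: int
    positive_individuals: tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortCallSummary:
    """Individual-level tallies per cohort group plus per-sample calls."""

    groups: dict[str, GroupCounts]
    excluded: tuple[tuple[str, str], ...]  # (individual_id, reason)
    calls: tuple[CallResult, ...] = field(default=())
    passage_filter: int | None = None
    threshold_fraction: float = float("nan")

    def total_individuals(self, group: str) -> int:
        n_excluded = sum(1 for ind, _ in self.excluded if ind.startswith(f"{group}:"))
        return self.groups[group].evaluable + n_excluded


def qc_pass(sample: AmpliconSample, min_depth: int = DEFAULT_MIN_DEPTH) -> bool:
    """True iff the sample's total read count reaches ``min_depth`` (inclusive)."""
    return sample.total_reads >= min_depth


def call_sample(
    sample: AmpliconSample,
    model: BackgroundModel,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> CallResult:
    """Call one sample against the background model.

    Positivity is a strict, full-precision comparison of the allele
    fraction with ``model.threshold_fraction``; it is left undefined
    (``None``) when QC fails.
    """
    if not qc_pass(sample, min_depth):
        return CallResult(
            sample_id=sample.sample_id,
            allele_fraction=(
                allele_fraction(sample.total_reads, sample.alt_reads)
                if sample.total_reads > 0
                else float("nan")
            ),
            qc_pass=False,
            qc_reason=f"total_reads {sample.total_reads} < min_depth {min_depth}",
        )
    af = allele_fraction(sample.total_reads, sample.alt_reads)
    return CallResult(
        sample_id=sample.sample_id,
        allele_fraction=af,
        qc_pass=True,
        positive=af > model.threshold_fraction,
    )


def call_cohort(
    table: CohortTable,
    model: BackgroundModel,
    min_depth: int = DEFAULT_MIN_DEPTH,
    passage_filter: int | None = None,
) -> CohortCallSummary:
    """Individual-level positivity tallies per cohort group.

    When ``passage_filter`` is given only samples at that passage are
    considered; an individual with several passing replicates is positive
    if any of them is.  Individuals whose selected samples all fail QC are
    listed in ``excluded`` with the failing reasons.
    """
    if passage_filter is not None:
        selected = [s for s in table if s.passage == passage_filter]
        if not selected:
            raise EmptySelectionError(f"no samples at passage {passage_filter}")
    else:
        selected = list(table)

    calls = {s.sample_id: call_sample(s, model, min_depth) for s in selected}

    per_group: dict[str, dict[str, list[str]]] = {}
    excluded: list[tuple[str, str]] = []
    seen_groups: list[str] = []
    by_individual: dict[tuple[str, str], list[AmpliconSample]] = {}
    for s in selected:
        g = s.cohort.value
        if g not in seen_groups:
            seen_groups.append(g)
        by_individual.setdefault((g, s.individual_id), []).append(s)

    for g in seen_groups:
        per_group[g] = {"evaluable": [], "positive": []}
    for (g, ind), samples in by_individual.items():
        ind_calls = [calls[s.sample_id] for s in samples]
        passing = [c for c in ind_calls if c.qc_pass]
        if not passing:
            reasons = "; ".join(c.qc_reason for c in ind_calls)
            excluded.append((f"{g}:{ind}", reasons))
            continue
        per_group[g]["evaluable"].append(ind)
        if any(c.positive for c in passing):
            per_group[g]["positive"].append(ind)

    groups = {
        g: GroupCounts(
            evaluable=len(d["evaluable"]),
            positive=len(d["positive"]),
            positive_individuals=tuple(d["positive"]),
        )
        for g, d in per_group.items()
    }
    return CohortCallSummary(
        groups=groups,
        excluded=tuple(excluded),
        calls=tuple(calls[s.sample_id] for s in selected),
        passage_filter=passage_filter,
        threshold_fraction=model.threshold_fraction,
    )
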