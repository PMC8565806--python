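"""Inclusion filtering, name/term normalization, and report -> event expansion.

The analysis pipeline keeps only pediatric reports whose reporter-assessed
causality is at least "possible", unifies raw drug strings to generic (API)
names and raw ADR strings to preferred terms, then expands each report into
drug-event combinations (DECs): one event per distinct (report, drug, ADR)
triple.  Events, not reports, are the counting unit of disproportionality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional

from .data_model import (
    ADRDictionary,
    ADRReport,
    Causality,
    DrugDictionary,
    DrugEventCombination,
)

#: machine-readable exclusion reason codes
REASON_AGE = "age"
REASON_AGE_UNKNOWN = "age_unknown"
REASON_CAUSALITY = "causality"
REASON_DRUG = "drug_class"

DEFAULT_CAUSALITY = frozenset({Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE})


@dataclass(frozen=True)
class InclusionCriteria:
    """Report inclusion rules: age window, causality levels, optional drug class."""

    age_min: int = 0
    age_max: int = 14
    causality_allowed: frozenset[Causality] = DEFAULT_CAUSALITY
    drug_class_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")
        if not self.causality_allowed:
            raise ValueError("causality_allowed must be non-empty")


class NormalizationLogEntry(NamedTuple):
    """A raw drug name or ADR term not found in its dictionary (kept verbatim)."""

    report_id: str
    field: str
    raw: str


class Exclusion(NamedTuple):
    report: ADRReport
    reason: str


class FilterResult(NamedTuple):
    included: list[ADRReport]
    excluded: list[Exclusion]


def _dedup(seq: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for s in seq:
        seen.setdefault(s, None)
    return tuple(seen)


def normalize_report(
    report: ADRReport,
    drug_dict: DrugDictionary,
    adr_dict: ADRDictionary,
    log: Optional[list[NormalizationLogEntry]] = None,
) -> ADRReport:
    """Map drugs to canonical names and ADR strings to preferred terms.

    Unmapped entries are kept verbatim (and logged when ``log`` is given);
    within-report duplicates arising from the mapping are removed, preserving
    first-occurrence order.
    """
    drugs = []
    for raw in report.drugs:
        canon = drug_dict.lookup(raw)
        if canon is None:
            if log is not None:
                log.append(NormalizationLogEntry(report.report_id, "drugs", raw))
            canon = raw
        drugs.append(canon)
    adrs = []
    for raw in report.adr_terms:
        pref = adr_dict.lookup(raw)
        if pref is None:
            if log is not None:
                log.append(NormalizationLogEntry(report.report_id, "adr_terms", raw))
            pref = raw
        adrs.append(pref)
    return replace(report, drugs=_dedup(drugs), adr_terms=_dedup(adrs))


def normalize_reports(
    reports: Iterable[ADRReport],
    drug_dict: DrugDictionary,
    adr_dict: ADRDictionary,
) -> tuple[list[ADRReport], list[NormalizationLogEntry]]:
    log: list[NormalizationLogEntry] = []
    out = [normalize_report(r, drug_dict, adr_dict, log) for r in reports]
    return out, log


def filter_reports(
    reports: Iterable[ADRReport],
    criteria: InclusionCriteria,
    *,
    unknown_age_policy: str = "include",
) -> FilterResult:
    """Partition reports into included and excluded-with-reason.

    Unknown-age reports are kept in the included set by default (they stay in
    overall totals and are only omitted from age breakdowns downstream);
    ``unknown_age_policy="exclude"`` drops them with reason ``age_unknown``.
    """
    if unknown_age_policy not in ("include", "exclude"):
        raise ValueError("unknown_age_policy must be 'include' or 'exclude'")
    included: list[ADRReport] = []
    excluded: list[Exclusion] = []
    for r in reports:
        if r.age_years is None:
            if unknown_age_policy == "exclude":
                excluded.append(Exclusion(r, REASON_AGE_UNKNOWN))
                continue
        elif not (criteria.age_min <= r.age_years <= criteria.age_max):
            excluded.append(Exclusion(r, REASON_AGE))
            continue
        if r.causality not in criteria.causality_allowed:
            excluded.append(Exclusion(r, REASON_CAUSALITY))
            continue
        if criteria.drug_class_filter is not None and not (
            set(r.drugs) & criteria.drug_class_filter
        ):
            excluded.append(Exclusion(r, REASON_DRUG))
            continue
        included.append(r)
    return FilterResult(included, excluded)


def expand_events(
    reports: Iterable[ADRReport], *, dedup: bool = True
) -> list[DrugEventCombination]:
    """Expand reports into DECs: the cartesian product of each report's drugs
    and ADR terms, one event per distinct (report, drug, adr) triple.

    Deterministic and order-independent: the result is sorted by
    (report_id, drug, adr).  With ``dedup=False`` repeated identical triples
    (possible only if the caller skipped normalization) are kept.
    """
    events: list[DrugEventCombination] = []
    for r in reports:
        drugs = _dedup(r.drugs) if dedup else r.drugs
        adrs = _dedup(r.adr_terms) if dedup else r.adr_terms
        for drug in drugs:
            for adr in adrs:
                events.append(DrugEventCombination(r.report_id, drug, adr))
    events.sort()
    return events
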