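"""Descriptive safety statistics for SRS report and event sets.

Covers the standard pharmacovigilance summary tables: sex ratio, severity
proportions (overall and stratified), ADR frequency at preferred-term and
system-organ-class level, administration routes, outcomes with a death-case
extract, and Pearson chi-square comparisons between strata.

Percentages are rounded half-up to two decimals, the precision such tables
are conventionally printed at.  Report-level tables use the number of reports
as denominator; event-level tables use the number of events — each
:class:`FrequencyTable` records its denominator explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .data_model import (
    ADRDictionary,
    ADRReport,
    DrugEventCombination,
    Outcome,
    Sex,
    Severity,
    Novelty,
)

UNCLASSIFIED_SOC = "unclassified"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, ndigits: int = 2) -> float:
    """Exact decimal percentage ``count/denominator*100`` rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(count) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class FrequencyRow:
    label: str
    count: int
    percent: float
    cumulative_percent: float


@dataclass(frozen=True)
class FrequencyTable:
    """Label/count/percent rows over an explicit denominator.

    When the labels are exhaustive the counts sum to the denominator; for
    truncated listings (e.g. "top 95%") they sum to less.  Cumulative
    percentages are computed from cumulative counts, so they are exact rather
    than sums of rounded row percentages.
    """

    rows: tuple[FrequencyRow, ...]
    denominator: int
    sort: str = "by_count_desc"

    @classmethod
    def from_counts(
        cls,
        pairs: Iterable[tuple[str, int]],
        denominator: int,
        sort: str = "by_count_desc",
    ) -> "FrequencyTable":
        pairs = list(pairs)
        if sort == "by_count_desc":
            pairs.sort(key=lambda p: (-p[1], p[0]))
        elif sort != "as_given":
            raise ValueError("sort must be 'by_count_desc' or 'as_given'")
        rows = []
        cum = 0
        for label, count in pairs:
            cum += count
            rows.append(
                FrequencyRow(label, count, percent(count, denominator), percent(cum, denominator))
            )
        return cls(tuple(rows), denominator, sort)

    def percent_of(self, label: str) -> float:
        for row in self.rows:
            if row.label == label:
                return row.percent
        raise KeyError(label)

    def cumulative_percent_of(self, label: str) -> float:
        for row in self.rows:
            if row.label == label:
                return row.cumulative_percent
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.rows],
                "count": [r.count for r in self.rows],
                "percent": [r.percent for r in self.rows],
                "cumulative_percent": [r.cumulative_percent for r in self.rows],
            }
        )


@dataclass(frozen=True)
class SeverityBreakdown:
    """Serious-report share within one stratum."""

    stratum: str
    n_serious: int
    n_total: int
    percent_serious: float

    @classmethod
    def from_counts(cls, stratum: str, n_serious: int, n_total: int) -> "SeverityBreakdown":
        if not 0 <= n_serious <= n_total:
            raise ValueError("need 0 <= n_serious <= n_total")
        return cls(stratum, n_serious, n_total, percent(n_serious, n_total))


class SexSummary(NamedTuple):
    n_male: int
    n_female: int
    n_unknown: int
    ratio: Optional[float]  # male:female, None when undefined (no females)


def sex_summary(reports: Iterable[ADRReport]) -> SexSummary:
    """Sex counts and the male:female ratio (unknowns excluded from the ratio)."""
    n_m = n_f = n_u = 0
    for r in reports:
        if r.sex is Sex.MALE:
            n_m += 1
        elif r.sex is Sex.FEMALE:
            n_f += 1
        else:
            n_u += 1
    ratio = None if n_f == 0 else round_half_up(n_m / n_f)
    return SexSummary(n_m, n_f, n_u, ratio)


class SeveritySummary(NamedTuple):
    overall: SeverityBreakdown
    n_new_serious: int
    n_new_non_serious: int


def severity_summary(reports: Iterable[ADRReport]) -> SeveritySummary:
    """Overall serious/non-serious split plus new-ADR sub-counts."""
    n_serious = n_total = n_new_s = n_new_ns = 0
    for r in reports:
        n_total += 1
        serious = r.severity is Severity.SERIOUS
        if serious:
            n_serious += 1
        if r.novelty is Novelty.NEW:
            if serious:
                n_new_s += 1
            else:
                n_new_ns += 1
    return SeveritySummary(
        SeverityBreakdown.from_counts("all", n_serious, n_total), n_new_s, n_new_ns
    )


#: named preset for the dichotomous age comparison (young children vs older)
AGE_PRESET_0_4_VS_5_14 = "0_4_vs_5_14"
AGE_PRESET_SINGLE_YEAR = "single_year"


def _age_stratum(age: Optional[int], preset: str) -> str:
    if age is None:
        return "unknown"
    if preset == AGE_PRESET_SINGLE_YEAR:
        return str(age)
    if preset == AGE_PRESET_0_4_VS_5_14:
        return "0-4" if age <= 4 else "5-14"
    raise ValueError(f"unknown age preset {preset!r}")


def severity_by_stratum(
    reports: Iterable[ADRReport],
    stratifier: str,
    *,
    age_preset: str = AGE_PRESET_SINGLE_YEAR,
) -> list[SeverityBreakdown]:
    """Serious-report share per stratum of ``sex``, ``age_group`` or ``drug``.

    Unknown sex/age form their own stratum.  In drug mode a report contributes
    to each of its distinct suspected drugs, and rows come back ordered by
    total count descending (the conventional per-drug table ordering); sex and
    age strata keep their natural order.
    """
    counts: dict[str, list[int]] = {}

    def bump(key: str, serious: bool) -> None:
        cell = counts.setdefault(key, [0, 0])
        cell[1] += 1
        if serious:
            cell[0] += 1

    for r in reports:
        serious = r.severity is Severity.SERIOUS
        if stratifier == "sex":
            bump(r.sex.value, serious)
        elif stratifier == "age_group":
            bump(_age_stratum(r.age_years, age_preset), serious)
        elif stratifier == "drug":
            for drug in dict.fromkeys(r.drugs):
                bump(drug, serious)
        else:
            raise ValueError("stratifier must be 'sex', 'age_group' or 'drug'")

    if stratifier == "drug":
        order = sorted(counts, key=lambda k: (-counts[k][1], k))
    elif stratifier == "sex":
        known = [s.value for s in Sex if s.value in counts]
        order = known
    else:  # age groups: numeric where possible, unknown last
        def age_key(k: str):
            head = k.split("-")[0]
            return (head.isdigit() is False, int(head) if head.isdigit() else 0, k)

        order = sorted(counts, key=age_key)
    return [SeverityBreakdown.from_counts(k, counts[k][0], counts[k][1]) for k in order]


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    p: float


def pearson_chi2(table: Sequence[Sequence[int]], yates: bool = False) -> Chi2Result:
    """Pearson chi-square test of independence on an r x c count table.

    The Yates continuity correction (|O-E| reduced by 0.5, clamped at zero)
    is applied only to 2x2 tables and only when requested.  A zero row or
    column margin is degenerate and raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate margin")
    n = obs.sum()
    expected = np.outer(row, col) / n
    dev = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_scipy_stats.chi2.sf(chi2, df))
    return Chi2Result(chi2, df, p)


def adr_frequency(
    events: Iterable[DrugEventCombination],
    adr_dict: Optional[ADRDictionary] = None,
    level: str = "term",
) -> FrequencyTable:
    """Event frequency per preferred term or per system-organ class.

    The denominator is the total number of events.  At SOC level, terms
    missing from the dictionary fall into the ``unclassified`` bucket.
    """
    events = list(events)
    counts: dict[str, int] = {}
    for ev in events:
        if level == "term":
            key = ev.adr
        elif level == "soc":
            soc = adr_dict.soc(ev.adr) if adr_dict is not None else None
            key = soc if soc is not None else UNCLASSIFIED_SOC
        else:
            raise ValueError("level must be 'term' or 'soc'")
        counts[key] = counts.get(key, 0) + 1
    return FrequencyTable.from_counts(counts.items(), denominator=len(events))


class OutcomeSummary(NamedTuple):
    table: FrequencyTable
    deaths: pd.DataFrame  # one row per death case: sex, age, drugs, ADRs


def outcome_summary(reports: Iterable[ADRReport]) -> OutcomeSummary:
    """Outcome distribution over reports plus a death-case extract."""
    reports = list(reports)
    counts: dict[str, int] = {}
    death_rows = []
    for r in reports:
        counts[r.outcome.value] = counts.get(r.outcome.value, 0) + 1
        if r.outcome is Outcome.DEATH:
            death_rows.append(
                {
                    "report_id": r.report_id,
                    "sex": r.sex.value,
                    "age_years": r.age_years,
                    "drugs": ";".join(r.drugs),
                    "adr_terms": ";".join(r.adr_terms),
                }
            )
    deaths = pd.DataFrame(
        death_rows, columns=["report_id", "sex", "age_years", "drugs", "adr_terms"]
    )
    return OutcomeSummary(
        FrequencyTable.from_counts(counts.items(), denominator=len(reports)), deaths
    )


def route_summary(reports: Iterable[ADRReport]) -> FrequencyTable:
    """Administration-route distribution over reports."""
    reports = list(reports)
    counts: dict[str, int] = {}
    for r in reports:
        counts[r.route.value] = counts.get(r.route.value, 0) + 1
    return FrequencyTable.from_counts(counts.items(), denominator=len(reports))
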