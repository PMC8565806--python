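"""Disproportionality signal mining on drug-event combinations.

For each drug-event combination (DEC) the event universe is collapsed to a
fourfold (2x2) table

    =============  ==========  ==========
    .              target ADR  other ADRs
    =============  ==========  ==========
    target drug    a           b
    other drugs    c           d
    =============  ==========  ==========

and three classical measures are applied:

* **ROR** (reporting odds ratio) ``ad/bc``; signal when ``a >= 3`` and the
  95% CI lower bound exceeds 1, with ``SE(ln ROR) = sqrt(1/a+1/b+1/c+1/d)``.
* **PRR** (proportional reporting ratio) ``[a/(a+b)] / [c/(c+d)]``; same
  criterion, with ``SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))``.
* **MHRA** composite: ``a >= 3``, ``PRR >= 2`` and Yates-corrected
  ``chi2 >= 4``.

A *consensus* signal is a DEC flagged by all three methods simultaneously.
Estimates are undefined (NaN, never flagged) when a zero cell makes the CI
incomputable; an optional Haldane-Anscombe +0.5 correction is available but
off by default.  Internal arithmetic is full precision; rounding to two
decimals is a display concern left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_model import DrugDictionary, DrugEventCombination


@dataclass(frozen=True)
class FourfoldTable:
    """Counts of one DEC against the rest of the event universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(a+b, c+d, a+c, b+d) row and column sums."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class SignalCriteria:
    """Signal thresholds shared by the three methods."""

    min_a: int = 3
    ci_lower_threshold: float = 1.0
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    z: float = 1.96

    def __post_init__(self) -> None:
        if min(self.min_a, self.ci_lower_threshold, self.prr_threshold,
               self.chi2_threshold, self.z) <= 0:
            raise ValueError("all thresholds must be > 0")


DEFAULT_CRITERIA = SignalCriteria()


class RatioResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    flag: bool


@dataclass(frozen=True)
class SignalResult:
    """Per-DEC disproportionality estimates, flags and consensus."""

    drug: str
    adr: str
    table: FourfoldTable
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2_yates: float
    flag_ror: bool
    flag_prr: bool
    flag_mhra: bool
    consensus: bool
    off_label: Optional[bool] = None  # None = no label data for this drug


def build_fourfold(
    events: Iterable[DrugEventCombination], drug: str, adr: str
) -> FourfoldTable:
    """Count the fourfold table for (drug, adr) against the supplied events.

    The supplied event set *is* the background scope; pass a larger universe
    to widen the background.
    """
    events = list(events)
    if not events:
        raise ValueError("background scope empty")
    a = b = c = d = 0
    for ev in events:
        if ev.drug == drug:
            if ev.adr == adr:
                a += 1
            else:
                b += 1
        elif ev.adr == adr:
            c += 1
        else:
            d += 1
    return FourfoldTable(a, b, c, d)


def _apply_haldane(t: FourfoldTable) -> tuple[float, float, float, float]:
    if min(t.a, t.b, t.c, t.d) == 0:
        return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def ror_stats(
    table: FourfoldTable,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    *,
    haldane: bool = False,
) -> RatioResult:
    """Reporting odds ratio with its normal-approximation 95% CI and flag.

    Any zero cell leaves the estimate undefined (NaN) and the flag false,
    unless the Haldane-Anscombe +0.5 correction is requested.
    """
    a, b, c, d = _apply_haldane(table) if haldane else (
        float(table.a), float(table.b), float(table.c), float(table.d)
    )
    if min(a, b, c, d) == 0:
        return RatioResult(math.nan, math.nan, math.nan, False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - criteria.z * se)
    hi = math.exp(math.log(ror) + criteria.z * se)
    flag = table.a >= criteria.min_a and lo > criteria.ci_lower_threshold
    return RatioResult(ror, lo, hi, flag)


def prr_stats(
    table: FourfoldTable,
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    *,
    haldane: bool = False,
) -> RatioResult:
    """Proportional reporting ratio with its 95% CI and flag.

    Undefined (NaN, unflagged) when ``a = 0`` or ``c = 0`` (or any cell is
    zero, since the SE needs all four margins positive) without Haldane
    correction.
    """
    a, b, c, d = _apply_haldane(table) if haldane else (
        float(table.a), float(table.b), float(table.c), float(table.d)
    )
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return RatioResult(math.nan, math.nan, math.nan, False)
    prr = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    if var <= 0 or prr <= 0:  # degenerate (e.g. b = 0 and d = 0)
        return RatioResult(math.nan, math.nan, math.nan, False)
    se = math.sqrt(var)
    lo = math.exp(math.log(prr) - criteria.z * se)
    hi = math.exp(math.log(prr) + criteria.z * se)
    flag = table.a >= criteria.min_a and lo > criteria.ci_lower_threshold
    return RatioResult(prr, lo, hi, flag)


def yates_chi2(table: FourfoldTable, *, printed_denominator: bool = False) -> float:
    """Yates-continuity-corrected chi-square of the fourfold table.

    ``chi2 = N (max(0, |ad - bc| - N/2))^2 / [(a+b)(c+d)(a+c)(b+d)]``; the
    correction is clamped at zero so near-independent tables score 0 rather
    than an inflated value.  NaN when a margin is zero.  The
    ``printed_denominator`` variant substitutes ``(a+b)(a+c)(b+c)(c+d)``, a
    nonstandard form occasionally seen in print, for comparison only.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    if printed_denominator:
        denom = (a + b) * (a + c) * (b + c) * (c + d)
    else:
        denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    dev = max(0.0, abs(a * d - b * c) - n / 2)
    return n * dev * dev / denom


def mhra_flag(table: FourfoldTable, criteria: SignalCriteria = DEFAULT_CRITERIA) -> bool:
    """Composite criterion: ``a >= 3``, ``PRR >= 2`` and Yates chi2 >= 4."""
    if table.a < criteria.min_a:
        return False
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if a == 0 or c == 0 or (c + d) == 0:
        return False
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = yates_chi2(table)
    return prr >= criteria.prr_threshold and not math.isnan(chi2) and chi2 >= criteria.chi2_threshold


def _events_frame(events: Union[Iterable[DrugEventCombination], pd.DataFrame]) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events[["report_id", "drug", "adr"]].copy()
    return pd.DataFrame(
        [(e.report_id, e.drug, e.adr) for e in events],
        columns=["report_id", "drug", "adr"],
    )


def mine_signals(
    events: Union[Iterable[DrugEventCombination], pd.DataFrame],
    criteria: SignalCriteria = DEFAULT_CRITERIA,
    *,
    haldane: bool = False,
    unit: str = "events",
) -> list[SignalResult]:
    """Score every DEC with ``a >= 1`` against the whole event background.

    ``unit="events"`` counts events (the default counting unit);
    ``unit="reports"`` counts distinct reports per cell instead.  Results are
    ordered by (drug, descending ROR, adr); undefined RORs sort last within
    their drug.  Sub-threshold DECs (``a < min_a``) are scored but can never
    flag, so callers can inspect them.
    """
    df = _events_frame(events)
    if df.empty:
        return []
    if unit == "events":
        grouped = df.groupby(["drug", "adr"], sort=True).size()
        drug_tot = df.groupby("drug").size()
        adr_tot = df.groupby("adr").size()
        n_total = len(df)
    elif unit == "reports":
        grouped = df.groupby(["drug", "adr"], sort=True)["report_id"].nunique()
        drug_tot = df.groupby("drug")["report_id"].nunique()
        adr_tot = df.groupby("adr")["report_id"].nunique()
        n_total = df["report_id"].nunique()
    else:
        raise ValueError("unit must be 'events' or 'reports'")

    drugs = grouped.index.get_level_values("drug")
    adrs = grouped.index.get_level_values("adr")
    a = grouped.to_numpy(dtype=np.int64)
    b = drug_tot.reindex(drugs).to_numpy(dtype=np.int64) - a
    c = adr_tot.reindex(adrs).to_numpy(dtype=np.int64) - a
    d = n_total - a - b - c

    results: list[SignalResult] = []
    for drug, adr, ai, bi, ci, di in zip(drugs, adrs, a, b, c, d):
        t = FourfoldTable(int(ai), int(bi), int(ci), int(di))
        ror = ror_stats(t, criteria, haldane=haldane)
        prr = prr_stats(t, criteria, haldane=haldane)
        chi2 = yates_chi2(t)
        f_mhra = mhra_flag(t, criteria)
        results.append(
            SignalResult(
                drug=str(drug),
                adr=str(adr),
                table=t,
                ror=ror.estimate,
                ror_ci=(ror.ci_low, ror.ci_high),
                prr=prr.estimate,
                prr_ci=(prr.ci_low, prr.ci_high),
                chi2_yates=chi2,
                flag_ror=ror.flag,
                flag_prr=prr.flag,
                flag_mhra=f_mhra,
                consensus=ror.flag and prr.flag and f_mhra,
            )
        )
    results.sort(
        key=lambda s: (s.drug, -(s.ror if not math.isnan(s.ror) else -math.inf), s.adr)
    )
    return results


def off_label_flags(
    signals: Sequence[SignalResult], drug_dict: DrugDictionary
) -> list[SignalResult]:
    """Set ``off_label`` per signal: True when the ADR is absent from the
    drug's labeled ADR set, ``None`` when the drug has no label data."""
    out = []
    for s in signals:
        label_set = drug_dict.label_adr_map.get(s.drug)
        if label_set is None:
            out.append(replace(s, off_label=None))
        else:
            out.append(replace(s, off_label=s.adr not in label_set))
    return out


def signals_to_frame(signals: Sequence[SignalResult], *, ndigits: int = 2) -> pd.DataFrame:
    """Flatten signals into the conventional output table (values rounded for
    display; the SignalResult objects keep full precision)."""
    rows = []
    for s in signals:
        rows.append(
            {
                "drug": s.drug,
                "adr": s.adr,
                "a": s.table.a,
                "b": s.table.b,
                "c": s.table.c,
                "d": s.table.d,
                "ror": round(s.ror, ndigits) if not math.isnan(s.ror) else "",
                "ror_ci_low": round(s.ror_ci[0], ndigits) if not math.isnan(s.ror_ci[0]) else "",
                "prr": round(s.prr, ndigits) if not math.isnan(s.prr) else "",
                "prr_ci_low": round(s.prr_ci[0], ndigits) if not math.isnan(s.prr_ci[0]) else "",
                "chi2_yates": round(s.chi2_yates, ndigits) if not math.isnan(s.chi2_yates) else "",
                "flag_ror": s.flag_ror,
                "flag_prr": s.flag_prr,
                "flag_mhra": s.flag_mhra,
                "consensus": s.consensus,
                "off_label": "" if s.off_label is None else s.off_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "adr", "a", "b", "c", "d", "ror", "ror_ci_low", "prr",
            "prr_ci_low", "chi2_yates", "flag_ror", "flag_prr", "flag_mhra",
            "consensus", "off_label",
        ],
    )
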