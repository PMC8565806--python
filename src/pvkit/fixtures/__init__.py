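"""Packaged reference tables from a published provincial-SRS cephalosporin
safety study in children (Hubei, 2014-2019; 15,857 included reports expanding
to 20,681 events).

The raw reports behind the study are confidential, so what ships here are the
*printed aggregate tables* transcribed to CSV: per-drug report counts, serious
counts per drug, system-organ-class and preferred-term event counts, the four
death cases, the 206 consensus signals with their off-label annotations, and
the headline summary counts.  They drive the descriptive acceptance tests and
give the synthetic generator realistic marginals.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def report_counts_by_drug() -> pd.DataFrame:
    """Per-drug report counts with generation labels (columns
    ``generation, drug, n``; 37 named drugs plus an unknown row; sums to 15,857)."""
    return _read("table3_report_counts.csv")


def serious_by_drug() -> pd.DataFrame:
    """Serious and total report counts per drug (``drug, n_serious, n_total``),
    ordered by total descending; serious counts sum to 1,052."""
    return _read("table4_serious_by_drug.csv")


def soc_event_counts() -> pd.DataFrame:
    """Top-10 system-organ-class event counts (``rank, soc, n``); the full
    denominator is 20,681 events over 21 organ classes."""
    return _read("table5_soc_counts.csv")


def adr_event_counts() -> pd.DataFrame:
    """Preferred-term event counts for the most frequent ADRs (``adr, n``).

    The listing is truncated (terms covering the top ~95%), so counts sum to
    less than the 20,681-event denominator.
    """
    return _read("table6_adr_counts.csv")


def death_cases() -> pd.DataFrame:
    """The four death cases (sex, age, drug, disease, dose, ADR)."""
    return _read("table7_deaths.csv")


def consensus_signals() -> pd.DataFrame:
    """The 206 drug-ADR pairs flagged by all three methods
    (``generation, drug, adr, off_label``); 73 carry the off-label mark."""
    df = _read("table9_signals.csv")
    df["off_label"] = df["off_label"].astype(bool)
    return df


def signal_derived_label_map() -> dict[str, frozenset[str]]:
    """Synthetic stand-in for product labeling, reconstructed from the
    published off-label annotations: per drug, the consensus-signal ADRs *not*
    marked off-label.  Real product labels list many more terms; this map only
    supports round-tripping the published off-label flags in tests.
    """
    df = consensus_signals()
    on_label = df[~df["off_label"]]
    return {
        drug: frozenset(group["adr"])
        for drug, group in on_label.groupby("drug")
    }


#: headline counts quoted in the study's running text.  improved_or_recovered
#: is not printed as a count; 15,727 is the unique integer consistent with the
#: printed 99.18% of 15,857 reports.
SUMMARY_COUNTS: dict[str, int] = {
    "total_database_reports": 420_114,
    "pediatric_reports": 60_433,
    "included_reports": 15_857,
    "events": 20_681,
    "male": 9_740,
    "female": 6_103,
    "sex_unknown": 14,
    "age_unknown": 6,
    "age_0_1": 3_145,
    "age_2_3": 2_361,
    "serious": 1_052,
    "non_serious": 14_805,
    "new_serious": 154,
    "new_non_serious": 1_573,
    "injection": 15_271,
    "oral": 581,
    "improved_or_recovered": 15_727,
    "deaths": 4,
    "ror_signals": 211,
    "prr_signals": 207,
    "mhra_signals": 376,
    "consensus_signals": 206,
    "off_label_signals": 73,
}


@dataclass(frozen=True)
class PaperTables:
    """Bundle of every transcribed table, for one-call access."""

    report_counts_by_drug: pd.DataFrame
    serious_by_drug: pd.DataFrame
    soc_event_counts: pd.DataFrame
    adr_event_counts: pd.DataFrame
    death_cases: pd.DataFrame
    consensus_signals: pd.DataFrame
    summary_counts: dict[str, int]


def paper_fixture() -> PaperTables:
    """All transcribed reference tables as typed inputs for descriptive tests."""
    return PaperTables(
        report_counts_by_drug=report_counts_by_drug(),
        serious_by_drug=serious_by_drug(),
        soc_event_counts=soc_event_counts(),
        adr_event_counts=adr_event_counts(),
        death_cases=death_cases(),
        consensus_signals=consensus_signals(),
        summary_counts=dict(SUMMARY_COUNTS),
    )
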