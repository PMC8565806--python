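"""Domain types and file I/O for spontaneous-reporting-system (SRS) tables.

A spontaneous reporting system collects voluntarily submitted adverse drug
reaction (ADR) case reports.  One :class:`ADRReport` is one submitted case:
demographics, the suspected drug(s), the observed ADR term(s), the reporter's
causality assessment, severity/novelty classification, outcome and route of
administration.  Signal mining operates not on reports but on
:class:`DrugEventCombination` rows — one (report, drug, ADR term) event.

Report tables and the dictionary files are plain UTF-8 CSV with a mandatory
header row; multi-valued drug/ADR cells use ``;`` as the intra-field
delimiter.  Writers are bit-stable: fixed column order, ``\\n`` line endings.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence, Union


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Causality(str, Enum):
    """Reporter-assigned drug-ADR relationship (six-level Chinese SRS scale)."""

    CERTAIN = "certain"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    UNLIKELY = "unlikely"
    UNASSESSABLE = "unassessable"
    UNKNOWN = "unknown"


class Severity(str, Enum):
    SERIOUS = "serious"
    NON_SERIOUS = "non_serious"


class Novelty(str, Enum):
    """Whether the ADR is listed in the drug's package insert."""

    NEW = "new"
    KNOWN = "known"


class Outcome(str, Enum):
    RECOVERED = "recovered"
    IMPROVED = "improved"
    SEQUELAE = "sequelae"
    DEATH = "death"
    UNKNOWN = "unknown"


class Route(str, Enum):
    INJECTION = "injection"
    ORAL = "oral"
    OTHER = "other"
    UNKNOWN = "unknown"


class Generation(str, Enum):
    """Cephalosporin generation (or any drug-class subdivision label)."""

    FIRST = "1st"
    SECOND = "2nd"
    THIRD = "3rd"
    FOURTH = "4th"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ADRReport:
    """One spontaneous ADR case report.

    ``drugs`` and ``adr_terms`` must each hold at least one entry; raw strings
    are kept verbatim until :func:`pvkit.preprocess.normalize_report` maps them
    through the dictionaries.  ``age_years`` and ``report_date`` are ``None``
    when unknown.
    """

    report_id: str
    drugs: tuple[str, ...]
    adr_terms: tuple[str, ...]
    sex: Sex = Sex.UNKNOWN
    age_years: int | None = None
    causality: Causality = Causality.UNKNOWN
    severity: Severity = Severity.NON_SERIOUS
    novelty: Novelty = Novelty.KNOWN
    outcome: Outcome = Outcome.UNKNOWN
    route: Route = Route.UNKNOWN
    report_date: dt.date | None = None
    allergy_history: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "adr_terms", tuple(self.adr_terms))
        if not self.drugs:
            raise ValueError(f"report {self.report_id!r}: drugs must be non-empty")
        if not self.adr_terms:
            raise ValueError(f"report {self.report_id!r}: adr_terms must be non-empty")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"report {self.report_id!r}: age_years must be >= 0")


@dataclass(frozen=True, order=True)
class DrugEventCombination:
    """One (report, drug, ADR term) event — the counting unit of signal mining.

    The same (drug, adr) pair within one report counts once.
    """

    report_id: str
    drug: str
    adr: str


@dataclass(frozen=True)
class DrugDictionary:
    """Drug-name synonym dictionary with optional class and label annotations.

    ``synonym_map`` maps raw report strings to canonical generic (API) names
    and is idempotent on canonical names.  ``label_adr_map`` holds, per
    canonical drug, the set of ADR preferred terms listed in its product
    labeling (used for off-label flagging).
    """

    synonym_map: Mapping[str, str]
    generation_map: Mapping[str, Generation] = field(default_factory=dict)
    label_adr_map: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def lookup(self, raw: str) -> str | None:
        """Canonical name for ``raw``, or ``None`` if unmapped."""
        return self.synonym_map.get(raw)

    def with_labels(self, label_adr_map: Mapping[str, Iterable[str]]) -> "DrugDictionary":
        return replace(
            self,
            label_adr_map={k: frozenset(v) for k, v in label_adr_map.items()},
        )


@dataclass(frozen=True)
class ADRDictionary:
    """WHO-ART-style term dictionary: raw string -> preferred term -> organ class."""

    term_map: Mapping[str, str]
    soc_map: Mapping[str, str]

    def lookup(self, raw: str) -> str | None:
        return self.term_map.get(raw)

    def soc(self, preferred: str) -> str | None:
        """System-organ class of a preferred term, ``None`` if unclassified."""
        return self.soc_map.get(preferred)


REPORT_COLUMNS = (
    "report_id",
    "sex",
    "age_years",
    "drugs",
    "adr_terms",
    "causality",
    "severity",
    "novelty",
    "outcome",
    "route",
    "report_date",
    "allergy_history",
)
#: columns that must be present in a report table (allergy_history is optional)
MANDATORY_COLUMNS = REPORT_COLUMNS[:-1]

LIST_DELIMITER = ";"


class ParseLogEntry(NamedTuple):
    """One field coerced to unknown (or dropped) during parsing."""

    report_id: str
    field: str
    raw: str


class ReadResult(NamedTuple):
    reports: list[ADRReport]
    parse_log: list[ParseLogEntry]


def _parse_enum(cls, raw, default, log, report_id, fieldname):
    text = raw.strip().lower().replace("-", "_").replace(" ", "_")
    if not text:
        return default
    try:
        return cls(text)
    except ValueError:
        log.append(ParseLogEntry(report_id, fieldname, raw))
        return default


def read_reports(
    path: Union[str, Path],
    *,
    delimiter: str = ",",
    list_delimiter: str = LIST_DELIMITER,
) -> ReadResult:
    """Read a report table.

    Unparseable enum / age / date values are coerced to their unknown state and
    recorded in the parse log.  Missing mandatory columns and duplicate
    ``report_id`` values are hard errors.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column: {col!r}")
        rows = list(reader)

    seen: dict[str, int] = {}
    for row in rows:
        rid = row["report_id"]
        seen[rid] = seen.get(rid, 0) + 1
    dups = sorted(rid for rid, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate report_id values: {dups}")

    reports: list[ADRReport] = []
    log: list[ParseLogEntry] = []
    for row in rows:
        rid = row["report_id"]
        raw_age = (row.get("age_years") or "").strip()
        age: int | None = None
        if raw_age:
            try:
                age = int(raw_age)
                if age < 0:
                    raise ValueError
            except ValueError:
                log.append(ParseLogEntry(rid, "age_years", raw_age))
                age = None
        raw_date = (row.get("report_date") or "").strip()
        date: dt.date | None = None
        if raw_date:
            try:
                date = dt.date.fromisoformat(raw_date)
            except ValueError:
                log.append(ParseLogEntry(rid, "report_date", raw_date))
        drugs = tuple(
            s.strip() for s in (row.get("drugs") or "").split(list_delimiter) if s.strip()
        )
        adrs = tuple(
            s.strip() for s in (row.get("adr_terms") or "").split(list_delimiter) if s.strip()
        )
        if not drugs:
            raise ValueError(f"report {rid!r}: empty drugs field")
        if not adrs:
            raise ValueError(f"report {rid!r}: empty adr_terms field")
        reports.append(
            ADRReport(
                report_id=rid,
                drugs=drugs,
                adr_terms=adrs,
                sex=_parse_enum(Sex, row.get("sex") or "", Sex.UNKNOWN, log, rid, "sex"),
                age_years=age,
                causality=_parse_enum(
                    Causality, row.get("causality") or "", Causality.UNKNOWN, log, rid, "causality"
                ),
                severity=_parse_enum(
                    Severity, row.get("severity") or "", Severity.NON_SERIOUS, log, rid, "severity"
                ),
                novelty=_parse_enum(
                    Novelty, row.get("novelty") or "", Novelty.KNOWN, log, rid, "novelty"
                ),
                outcome=_parse_enum(
                    Outcome, row.get("outcome") or "", Outcome.UNKNOWN, log, rid, "outcome"
                ),
                route=_parse_enum(Route, row.get("route") or "", Route.UNKNOWN, log, rid, "route"),
                report_date=date,
                allergy_history=(row.get("allergy_history") or "").strip(),
            )
        )
    return ReadResult(reports, log)


def write_reports(
    reports: Sequence[ADRReport],
    path: Union[str, Path],
    *,
    list_delimiter: str = LIST_DELIMITER,
) -> Path:
    """Write a report table; ``read_reports`` round-trips it exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.report_id,
                    r.sex.value,
                    "" if r.age_years is None else r.age_years,
                    list_delimiter.join(r.drugs),
                    list_delimiter.join(r.adr_terms),
                    r.causality.value,
                    r.severity.value,
                    r.novelty.value,
                    r.outcome.value,
                    r.route.value,
                    "" if r.report_date is None else r.report_date.isoformat(),
                    r.allergy_history,
                ]
            )
    return path


def _check_idempotent(mapping: dict[str, str], what: str) -> dict[str, str]:
    # canonical targets must map to themselves; chained/cyclic entries rejected
    out = dict(mapping)
    for target in set(mapping.values()):
        if target in out:
            if out[target] != target:
                raise ValueError(
                    f"{what}: {target!r} is both a canonical target and a synonym "
                    f"of {out[target]!r} (chained or cyclic mapping)"
                )
        else:
            out[target] = target
    return out


def load_dictionary(
    path: Union[str, Path], *, delimiter: str = ","
) -> Union[DrugDictionary, ADRDictionary]:
    """Load a drug-synonym or ADR-term dictionary, detected from the header.

    Drug dictionaries have columns ``synonym,canonical[,generation]``; ADR
    dictionaries have ``term,preferred,soc``.  A synonym mapped to two
    different canonicals is a hard error, as are chained/cyclic mappings.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        rows = [{k.strip().lower(): (v or "").strip() for k, v in row.items()} for row in reader]

    if "synonym" in header and "canonical" in header:
        synonym_map: dict[str, str] = {}
        generation_map: dict[str, Generation] = {}
        for row in rows:
            syn, canon = row["synonym"], row["canonical"]
            if not syn or not canon:
                continue
            if syn in synonym_map and synonym_map[syn] != canon:
                raise ValueError(
                    f"synonym {syn!r} mapped to both {synonym_map[syn]!r} and {canon!r}"
                )
            synonym_map[syn] = canon
            gen = row.get("generation", "")
            if gen:
                try:
                    generation_map[canon] = Generation(gen)
                except ValueError:
                    generation_map[canon] = Generation.UNKNOWN
        synonym_map = _check_idempotent(synonym_map, "drug dictionary")
        return DrugDictionary(synonym_map=synonym_map, generation_map=generation_map)

    if "term" in header and "preferred" in header:
        term_map: dict[str, str] = {}
        soc_map: dict[str, str] = {}
        for row in rows:
            term, pref = row["term"], row["preferred"]
            if not term or not pref:
                continue
            if term in term_map and term_map[term] != pref:
                raise ValueError(
                    f"term {term!r} mapped to both {term_map[term]!r} and {pref!r}"
                )
            term_map[term] = pref
            soc = row.get("soc", "")
            if soc:
                if pref in soc_map and soc_map[pref] != soc:
                    raise ValueError(f"preferred term {pref!r} assigned two organ classes")
                soc_map[pref] = soc
        term_map = _check_idempotent(term_map, "ADR dictionary")
        return ADRDictionary(term_map=term_map, soc_map=soc_map)

    raise ValueError(
        "unrecognized dictionary header: expected synonym,canonical[,generation] "
        "or term,preferred,soc"
    )


def load_drug_labels(path: Union[str, Path], *, delimiter: str = ",") -> dict[str, frozenset[str]]:
    """Load a drug -> on-label ADR table (columns ``drug,adr``)."""
    path = Path(path)
    labels: dict[str, set[str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        if "drug" not in header or "adr" not in header:
            raise ValueError("label table must have columns drug,adr")
        for row in reader:
            drug = (row.get("drug") or "").strip()
            adr = (row.get("adr") or "").strip()
            if drug and adr:
                labels.setdefault(drug, set()).add(adr)
    return {k: frozenset(v) for k, v in labels.items()}
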