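"""Synthetic spontaneous-report generator with implantable drug-ADR signals.

Real SRS databases are confidential, so every pipeline stage is exercised on
simulated report sets that share the statistical structure the analysis
assumes: one suspected drug per report drawn from catalog marginals, a
zero-truncated Poisson number of ADR terms per report, terms drawn from
baseline probabilities that an *implant* multiplies by a rate ratio within the
target drug's reports (renormalized) — the relative-reporting-rate mechanism
the PRR estimates.  Demographics, severity, outcome and route are drawn from
configurable marginal distributions.

Defaults mirror a large pediatric cephalosporin SRS extract: ~15,857 reports,
events/reports ratio 1.304, 6.63% serious, the published drug and ADR
marginals (see :mod:`pvkit.fixtures`).  A fixed seed makes the output
byte-identical across runs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import poisson as _poisson

from .data_model import (
    ADRReport,
    Causality,
    Novelty,
    Outcome,
    Route,
    Severity,
    Sex,
)
from .disproportionality import SignalResult
from . import fixtures

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DrugSpec:
    name: str
    probability: float
    generation: str = "unknown"


@dataclass(frozen=True)
class AdrSpec:
    term: str
    probability: float
    soc: str = "unclassified"
    serious_probability: float = 0.0663


@dataclass(frozen=True)
class Implant:
    """Multiplies one ADR's within-drug reporting probability by ``rate_ratio``.

    ``rate_ratio == 1`` is the null; ``> 1`` implants a positive association.
    """

    drug: str
    adr: str
    rate_ratio: float

    def __post_init__(self) -> None:
        if self.rate_ratio < 0:
            raise ValueError("rate_ratio must be >= 0")


def _check_probs(values: Sequence[float], what: str) -> None:
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{what}: probabilities must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError(f"{what}: probabilities must sum to 1 (got {arr.sum():.8f})")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one synthetic SRS database."""

    n_reports: int
    drugs: tuple[DrugSpec, ...]
    adrs: tuple[AdrSpec, ...]
    adr_per_report_mean: float = 1.3043
    implants: tuple[Implant, ...] = ()
    sex_probs: tuple[float, float, float] = (0.61423, 0.38489, 0.00088)  # m, f, unknown
    age_probs: tuple[float, ...] = ()  # over ages 0..14; default built in __post_init__
    age_unknown_prob: float = 6 / 15857
    causality_probs: tuple[float, float, float] = (0.05, 0.55, 0.40)  # certain/probable/possible
    new_prob: float = 1727 / 15857
    outcome_probs: tuple[float, float, float, float, float] = (
        0.60, 0.3918, 0.004, 0.00025, 0.00395,
    )  # recovered, improved, sequelae, death, unknown
    route_probs: tuple[float, float, float, float] = (0.9630, 0.0366, 0.0002, 0.0002)
    multi_drug_prob: float = 0.0  # chance of a second independently drawn drug
    serious_prob_by_drug: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if not self.drugs or not self.adrs:
            raise ValueError("drug and ADR catalogs must be non-empty")
        if self.adr_per_report_mean < 1:
            raise ValueError("adr_per_report_mean must be >= 1 (every report has an ADR)")
        _check_probs([d.probability for d in self.drugs], "drug catalog")
        _check_probs([a.probability for a in self.adrs], "ADR catalog")
        _check_probs(self.sex_probs, "sex_probs")
        _check_probs(self.causality_probs, "causality_probs")
        _check_probs(self.outcome_probs, "outcome_probs")
        _check_probs(self.route_probs, "route_probs")
        if not self.age_probs:
            object.__setattr__(self, "age_probs", _default_age_probs())
        _check_probs(self.age_probs, "age_probs")
        names = {d.name for d in self.drugs}
        terms = {a.term for a in self.adrs}
        for imp in self.implants:
            if imp.drug not in names:
                raise ValueError(f"implant drug {imp.drug!r} not in catalog")
            if imp.adr not in terms:
                raise ValueError(f"implant ADR {imp.adr!r} not in catalog")


def _default_age_probs() -> tuple[float, ...]:
    # bins 0-1 and 2-3 hold 3145 and 2361 of 15,851 known-age reports; the
    # remainder is spread evenly over ages 4-14
    w = np.array([3145 / 2] * 2 + [2361 / 2] * 2 + [(15851 - 3145 - 2361) / 11] * 11)
    w /= w.sum()
    return tuple(w)


def _zt_poisson_rate(mean: float) -> float:
    """Rate lambda of a zero-truncated Poisson with the given mean (>= 1)."""
    if mean <= 1.0 + 1e-12:
        return 1e-9
    return float(brentq(lambda lam: lam / (1 - math.exp(-lam)) - mean, 1e-9, 60.0))


def _adr_prob_matrix(config: SyntheticConfig) -> np.ndarray:
    """Per-drug ADR probability rows: baseline x implant rate ratios, renormalized."""
    base = np.array([a.probability for a in config.adrs], dtype=float)
    names = [d.name for d in config.drugs]
    terms = {a.term: j for j, a in enumerate(config.adrs)}
    mat = np.tile(base, (len(names), 1))
    for imp in config.implants:
        i = names.index(imp.drug)
        mat[i, terms[imp.adr]] *= imp.rate_ratio
    rowsum = mat.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("a drug's ADR probability row is all zero")
    return mat / rowsum


def generate_reports(config: SyntheticConfig) -> list[ADRReport]:
    """Draw a full synthetic report set; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    if n == 0:
        return []

    drug_names = [d.name for d in config.drugs]
    drug_p = np.array([d.probability for d in config.drugs], dtype=float)
    drug_p /= drug_p.sum()
    drug_idx = rng.choice(len(drug_names), size=n, p=drug_p)

    lam = _zt_poisson_rate(config.adr_per_report_mean)
    # zero-truncated Poisson via inverse CDF mapped onto the untruncated
    # quantile function: exact, vectorized, and safe for lambda -> 0
    p0 = math.exp(-lam)
    u = rng.random(n)
    k = _poisson.ppf(p0 + u * (1 - p0), lam).astype(np.int64)
    k = np.maximum(k, 1)

    prob = _adr_prob_matrix(config)  # D x T
    with np.errstate(divide="ignore"):
        logp = np.log(prob)
    n_avail = (prob > 0).sum(axis=1)
    k = np.minimum(k, n_avail[drug_idx])
    # Gumbel top-k == successive weighted sampling without replacement
    scores = logp[drug_idx] + rng.gumbel(size=(n, prob.shape[1]))
    order = np.argsort(-scores, axis=1)

    sex_vals = rng.choice(3, size=n, p=np.asarray(config.sex_probs))
    ages = rng.choice(len(config.age_probs), size=n, p=np.asarray(config.age_probs))
    age_unknown = rng.random(n) < config.age_unknown_prob
    causality_vals = rng.choice(3, size=n, p=np.asarray(config.causality_probs))
    serious_p = np.full(n, _default_serious_prob(config))
    override = dict(config.serious_prob_by_drug)
    if override:
        per_drug = np.array(
            [override.get(name, _default_serious_prob(config)) for name in drug_names]
        )
        serious_p = per_drug[drug_idx]
    serious = rng.random(n) < serious_p
    new = rng.random(n) < config.new_prob
    outcome_vals = rng.choice(5, size=n, p=np.asarray(config.outcome_probs))
    route_vals = rng.choice(4, size=n, p=np.asarray(config.route_probs))
    day_offsets = rng.integers(0, 2191, size=n)  # six report years
    second_drug = rng.random(n) < config.multi_drug_prob
    second_idx = rng.choice(len(drug_names), size=n, p=drug_p)

    sex_enum = (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)
    causality_enum = (Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE)
    outcome_enum = (Outcome.RECOVERED, Outcome.IMPROVED, Outcome.SEQUELAE,
                    Outcome.DEATH, Outcome.UNKNOWN)
    route_enum = (Route.INJECTION, Route.ORAL, Route.OTHER, Route.UNKNOWN)
    terms = [a.term for a in config.adrs]
    epoch = dt.date(2014, 1, 1)

    width = max(6, len(str(n)))
    reports: list[ADRReport] = []
    for i in range(n):
        drugs = [drug_names[drug_idx[i]]]
        if second_drug[i] and drug_names[second_idx[i]] not in drugs:
            drugs.append(drug_names[second_idx[i]])
        adr_terms = tuple(terms[j] for j in order[i, : k[i]])
        reports.append(
            ADRReport(
                report_id=f"S{i:0{width}d}",
                drugs=tuple(drugs),
                adr_terms=adr_terms,
                sex=sex_enum[sex_vals[i]],
                age_years=None if age_unknown[i] else int(ages[i]),
                causality=causality_enum[causality_vals[i]],
                severity=Severity.SERIOUS if serious[i] else Severity.NON_SERIOUS,
                novelty=Novelty.NEW if new[i] else Novelty.KNOWN,
                outcome=outcome_enum[outcome_vals[i]],
                route=route_enum[route_vals[i]],
                report_date=epoch + dt.timedelta(days=int(day_offsets[i])),
            )
        )
    return reports


def _default_serious_prob(config: SyntheticConfig) -> float:
    # catalog-level serious probabilities are uniform by default; use the mean
    return float(np.mean([a.serious_probability for a in config.adrs]))


def dataset_hash(reports: Iterable[ADRReport]) -> str:
    """SHA-256 over a canonical serialization; equal for identical datasets."""
    h = hashlib.sha256()
    for r in reports:
        h.update(
            "|".join(
                [
                    r.report_id, r.sex.value, str(r.age_years),
                    ";".join(r.drugs), ";".join(r.adr_terms),
                    r.causality.value, r.severity.value, r.novelty.value,
                    r.outcome.value, r.route.value, str(r.report_date),
                ]
            ).encode()
        )
        h.update(b"\n")
    return h.hexdigest()


def default_config(
    n_reports: int = 15_857,
    seed: int = 0,
    implants: Sequence[Implant] = (),
    **overrides,
) -> SyntheticConfig:
    """Catalog-backed default configuration.

    Drug marginals follow the published per-drug report counts and ADR
    baselines the published event counts (:mod:`pvkit.fixtures`); the ADR
    count per report is zero-truncated Poisson with mean 1.3043
    (20,681 events / 15,857 reports).
    """
    t3 = fixtures.report_counts_by_drug()
    t3 = t3[t3["drug"] != "Unknown"]
    total = t3["n"].sum()
    drugs = tuple(
        DrugSpec(row.drug, row.n / total, row.generation) for row in t3.itertuples()
    )
    t6 = fixtures.adr_event_counts()
    t6_total = t6["n"].sum()
    soc = _TERM_SOC
    adrs = tuple(
        AdrSpec(row.adr, row.n / t6_total, soc.get(row.adr, "unclassified"))
        for row in t6.itertuples()
    )
    return SyntheticConfig(
        n_reports=n_reports,
        drugs=drugs,
        adrs=adrs,
        implants=tuple(implants),
        seed=seed,
        **overrides,
    )


#: organ-class assignment for the default ADR catalog (WHO-ART-style SOCs)
_TERM_SOC = {
    "rash": "skin and appendages disorders",
    "pruritus": "skin and appendages disorders",
    "urticaria": "skin and appendages disorders",
    "maculo-papular rash": "skin and appendages disorders",
    "erythematous rash": "skin and appendages disorders",
    "dermatitis": "skin and appendages disorders",
    "allergic reaction": "body as a whole-general disorders",
    "face oedema": "body as a whole-general disorders",
    "fever": "body as a whole-general disorders",
    "rigors": "body as a whole-general disorders",
    "anaphylactoid reaction": "body as a whole-general disorders",
    "vomiting": "gastro-intestinal system disorders",
    "nausea": "gastro-intestinal system disorders",
    "abdominal pain": "gastro-intestinal system disorders",
    "diarrhoea": "gastro-intestinal system disorders",
    "dyspnoea": "respiratory system disorders",
    "coughing": "respiratory system disorders",
    "flushing": "autonomic nervous system disorders",
    "cyanosis": "autonomic nervous system disorders",
    "dizziness": "central and peripheral nervous system disorders",
    "palpitation": "heart rate and rhythm disorders",
    "agitation": "psychiatric disorders",
}


def choose_implants(
    config: SyntheticConfig,
    n_implants: int,
    rate_ratio: float,
    baseline_range: tuple[float, float] = (0.004, 0.06),
) -> SyntheticConfig:
    """Deterministically implant ``n_implants`` distinct (drug, adr) pairs.

    Drugs are taken in descending marginal order and ADR terms in descending
    baseline order restricted to ``baseline_range`` (common enough to detect,
    rare enough that the rate ratio survives renormalization).  Pair ``i`` is
    (drug ``i`` mod n_drugs, adr ``i`` mod n_adrs), so implants spread across
    drugs rather than piling onto one and distorting its within-drug
    renormalization.
    """
    drugs = sorted(config.drugs, key=lambda d: (-d.probability, d.name))
    adrs = [
        a for a in sorted(config.adrs, key=lambda a: (-a.probability, a.term))
        if baseline_range[0] <= a.probability <= baseline_range[1]
    ]
    if not adrs:
        raise ValueError("no catalog ADRs inside baseline_range")
    implants = []
    seen = set()
    i = 0
    while len(implants) < n_implants:
        pair = (drugs[i % len(drugs)].name, adrs[i % len(adrs)].term)
        i += 1
        if pair in seen:
            continue
        seen.add(pair)
        implants.append(Implant(pair[0], pair[1], rate_ratio))
    return replace(config, implants=tuple(implants))


class MethodRecovery(NamedTuple):
    sensitivity: Optional[float]  # None when there are no positives
    specificity: Optional[float]  # None when there are no scored negatives
    fdp: float  # false-discovery proportion; 0.0 when nothing is flagged
    n_flagged: int


@dataclass(frozen=True)
class RecoveryReport:
    """Detection performance of each method against the implanted truth."""

    per_method: dict[str, MethodRecovery]
    per_implant: dict[tuple[str, str], bool]  # consensus detection indicator


_METHOD_ATTR = {
    "ror": "flag_ror",
    "prr": "flag_prr",
    "mhra": "flag_mhra",
    "consensus": "consensus",
}


def evaluate_recovery(
    signals: Sequence[SignalResult], config: SyntheticConfig
) -> RecoveryReport:
    """Score mined signals against the config's implanted associations.

    Implants with ``rate_ratio > 1`` are the positives; every other scored DEC
    is a negative.  An implanted pair that never reached the scored universe
    counts as missed.
    """
    catalog_drugs = {d.name for d in config.drugs}
    signal_drugs = {s.drug for s in signals}
    if signals and not (catalog_drugs & signal_drugs):
        raise ValueError("signals and config share no drugs: wrong config?")

    positives = {(i.drug, i.adr) for i in config.implants if i.rate_ratio > 1}
    scored = {(s.drug, s.adr) for s in signals}
    per_method: dict[str, MethodRecovery] = {}
    for method, attr in _METHOD_ATTR.items():
        flagged = {(s.drug, s.adr) for s in signals if getattr(s, attr)}
        tp = flagged & positives
        fp = flagged - positives
        negatives = scored - positives
        sens = len(tp) / len(positives) if positives else None
        spec = 1 - len(fp) / len(negatives) if negatives else None
        fdp = len(fp) / len(flagged) if flagged else 0.0
        per_method[method] = MethodRecovery(sens, spec, fdp, len(flagged))
    consensus_set = {(s.drug, s.adr) for s in signals if s.consensus}
    per_implant = {p: p in consensus_set for p in positives}
    return RecoveryReport(per_method=per_method, per_implant=per_implant)
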