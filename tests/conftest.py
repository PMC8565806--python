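import datetime as dt

import pytest

from pvkit.data_model import (
    ADRDictionary,
    ADRReport,
    Causality,
    DrugDictionary,
    Novelty,
    Outcome,
    Route,
    Severity,
    Sex,
)


def make_report(report_id="r1", **kwargs):
    base = dict(
        report_id=report_id,
        drugs=("cefazolin",),
        adr_terms=("rash",),
        sex=Sex.MALE,
        age_years=3,
        causality=Causality.PROBABLE,
        severity=Severity.NON_SERIOUS,
        novelty=Novelty.KNOWN,
        outcome=Outcome.RECOVERED,
        route=Route.INJECTION,
        report_date=dt.date(2016, 5, 1),
    )
    base.update(kwargs)
    return ADRReport(**base)


@pytest.fixture
def toy_reports():
    return [
        make_report("r1", sex=Sex.MALE, age_years=1),
        make_report("r2", sex=Sex.FEMALE, age_years=2, drugs=("ceftriaxone",),
                    adr_terms=("rash", "vomiting"), severity=Severity.SERIOUS,
                    novelty=Novelty.NEW),
        make_report("r3", sex=Sex.MALE, age_years=7, outcome=Outcome.IMPROVED,
                    route=Route.ORAL),
        make_report("r4", sex=Sex.UNKNOWN, age_years=None, causality=Causality.POSSIBLE),
        make_report("r5", sex=Sex.FEMALE, age_years=14, outcome=Outcome.DEATH,
                    severity=Severity.SERIOUS, adr_terms=("anaphylactic shock",)),
    ]


@pytest.fixture
def drug_dict():
    return DrugDictionary(
        synonym_map={
            "Cefazolin Na": "cefazolin",
            "cefazolin": "cefazolin",
            "头孢唑肟": "ceftizoxime",
            "ceftizoxime": "ceftizoxime",
            "ceftriaxone": "ceftriaxone",
        },
        label_adr_map={"cefazolin": frozenset({"rash", "nausea"})},
    )


@pytest.fixture
def adr_dict():
    return ADRDictionary(
        term_map={
            "skin rash": "rash",
            "rash": "rash",
            "itching": "pruritus",
            "pruritus": "pruritus",
            "vomiting": "vomiting",
        },
        soc_map={
            "rash": "skin and appendages disorders",
            "pruritus": "skin and appendages disorders",
            "vomiting": "gastro-intestinal system disorders",
        },
    )
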