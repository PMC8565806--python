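import numpy as np
import pytest

from pvkit.data_model import Severity
from pvkit.disproportionality import build_fourfold, mine_signals
from pvkit.preprocess import expand_events
from pvkit.synthetic import (
    AdrSpec,
    DrugSpec,
    Implant,
    SyntheticConfig,
    choose_implants,
    dataset_hash,
    default_config,
    evaluate_recovery,
    generate_reports,
)


def small_config(**kwargs):
    base = dict(
        n_reports=100,
        drugs=(DrugSpec("d1", 0.5), DrugSpec("d2", 0.5)),
        adrs=(AdrSpec("a1", 0.6), AdrSpec("a2", 0.4)),
        seed=1,
    )
    base.update(kwargs)
    return SyntheticConfig(**base)


def test_zero_reports_gives_empty_list():
    assert generate_reports(small_config(n_reports=0)) == []


def test_single_drug_single_adr_is_degenerate():
    cfg = small_config(
        drugs=(DrugSpec("d1", 1.0),),
        adrs=(AdrSpec("a1", 1.0),),
        adr_per_report_mean=1.0,
        n_reports=50,
    )
    events = expand_events(generate_reports(cfg))
    assert len(events) == 50
    assert {(e.drug, e.adr) for e in events} == {("d1", "a1")}


def test_determinism_same_seed_same_hash():
    cfg = default_config(n_reports=800, seed=42)
    h1 = dataset_hash(generate_reports(cfg))
    h2 = dataset_hash(generate_reports(cfg))
    assert h1 == h2
    h3 = dataset_hash(generate_reports(default_config(n_reports=800, seed=43)))
    assert h3 != h1


def test_invalid_probability_vectors_rejected():
    with pytest.raises(ValueError, match="drug catalog"):
        small_config(drugs=(DrugSpec("d1", 0.7), DrugSpec("d2", 0.7)))
    with pytest.raises(ValueError, match="sex_probs"):
        small_config(sex_probs=(0.9, 0.9, 0.1))


def test_implant_must_reference_catalog():
    with pytest.raises(ValueError, match="not in catalog"):
        small_config(implants=(Implant("nope", "a1", 5.0),))


def test_events_per_report_matches_truncated_poisson_mean():
    cfg = default_config(n_reports=20_000, seed=7)
    reports = generate_reports(cfg)
    ratio = len(expand_events(reports)) / len(reports)
    # zero-truncated Poisson with mean 1.3043; Monte-Carlo slack at n=20,000
    assert ratio == pytest.approx(1.3043, rel=0.02)


def test_implanted_rate_ratio_recovered_empirically():
    # one implant at rate ratio 10 on a 1%-baseline term, one ADR per report:
    # the within-drug share is 10p/(1 + 9p) after renormalization, so the
    # expected observed reporting-rate ratio is that over the background p.
    p = 0.01
    rr = 10.0
    adrs = (AdrSpec("target", p), AdrSpec("filler1", 0.59), AdrSpec("filler2", 0.40))
    cfg = small_config(
        n_reports=50_000,
        drugs=(DrugSpec("d1", 0.2), DrugSpec("d2", 0.8)),
        adrs=adrs,
        adr_per_report_mean=1.0,
        implants=(Implant("d1", "target", rr),),
        seed=11,
    )
    events = expand_events(generate_reports(cfg))
    t = build_fourfold(events, "d1", "target")
    observed = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    expected = (rr * p / (1 + (rr - 1) * p)) / p
    assert observed == pytest.approx(expected, rel=0.10)


def test_marginal_serious_fraction():
    cfg = default_config(n_reports=30_000, seed=3)
    reports = generate_reports(cfg)
    frac = sum(r.severity is Severity.SERIOUS for r in reports) / len(reports)
    assert frac == pytest.approx(0.0663, abs=0.005)


def test_serious_probability_override_by_drug():
    cfg = default_config(
        n_reports=30_000,
        seed=5,
        serious_prob_by_drug=(("Ceftezole", 0.5),),
    )
    reports = generate_reports(cfg)
    target = [r for r in reports if r.drugs[0] == "Ceftezole"]
    frac = sum(r.severity is Severity.SERIOUS for r in target) / len(target)
    assert frac == pytest.approx(0.5, abs=0.03)


def test_choose_implants_distinct_and_in_range():
    cfg = choose_implants(default_config(n_reports=10), 20, 5.0)
    pairs = [(i.drug, i.adr) for i in cfg.implants]
    assert len(pairs) == len(set(pairs)) == 20
    baselines = {a.term: a.probability for a in cfg.adrs}
    for imp in cfg.implants:
        assert 0.004 <= baselines[imp.adr] <= 0.06
        assert imp.rate_ratio == 5.0


def test_recovery_perfect_detection():
    cfg = small_config(implants=(Implant("d1", "a1", 5.0),))
    # hand-built signal list: the implant flagged by everything, one unflagged DEC
    from pvkit.disproportionality import FourfoldTable, SignalResult

    def sig(drug, adr, flag):
        return SignalResult(
            drug=drug, adr=adr, table=FourfoldTable(5, 5, 5, 5),
            ror=2.0, ror_ci=(1.5, 3.0), prr=2.0, prr_ci=(1.5, 3.0), chi2_yates=10.0,
            flag_ror=flag, flag_prr=flag, flag_mhra=flag, consensus=flag,
        )

    rec = evaluate_recovery([sig("d1", "a1", True), sig("d2", "a2", False)], cfg)
    cons = rec.per_method["consensus"]
    assert cons.sensitivity == 1.0 and cons.fdp == 0.0
    assert rec.per_implant[("d1", "a1")] is True


def test_recovery_null_config_sensitivity_not_applicable():
    cfg = small_config()
    from pvkit.disproportionality import FourfoldTable, SignalResult

    s = SignalResult(
        drug="d1", adr="a1", table=FourfoldTable(5, 5, 5, 5),
        ror=1.0, ror_ci=(0.5, 2.0), prr=1.0, prr_ci=(0.5, 2.0), chi2_yates=0.0,
        flag_ror=False, flag_prr=False, flag_mhra=False, consensus=False,
    )
    rec = evaluate_recovery([s], cfg)
    assert rec.per_method["consensus"].sensitivity is None


def test_recovery_disjoint_universes_rejected():
    cfg = small_config()
    from pvkit.disproportionality import FourfoldTable, SignalResult

    s = SignalResult(
        drug="zz", adr="yy", table=FourfoldTable(1, 1, 1, 1),
        ror=1.0, ror_ci=(0.5, 2.0), prr=1.0, prr_ci=(0.5, 2.0), chi2_yates=0.0,
        flag_ror=False, flag_prr=False, flag_mhra=False, consensus=False,
    )
    with pytest.raises(ValueError, match="no drugs"):
        evaluate_recovery([s], cfg)


def test_null_flag_rate_small_and_consensus_below_each_method():
    cfg = default_config(n_reports=30_000, seed=19)  # no implants: global null
    signals = mine_signals(expand_events(generate_reports(cfg)))
    n = len(signals)
    fracs = {
        m: sum(getattr(s, a) for s in signals) / n
        for m, a in [("ror", "flag_ror"), ("prr", "flag_prr"), ("mhra", "flag_mhra"),
                     ("consensus", "consensus")]
    }
    for m in ("ror", "prr", "mhra"):
        assert fracs["consensus"] <= fracs[m]
    assert fracs["consensus"] < 0.10


def test_sensitivity_monotone_in_rate_ratio_and_size():
    # consensus sensitivity should not degrade as the implanted effect or the
    # database grows; checked on a small grid with averaged seeds
    def sens(n_reports, rr):
        vals = []
        for seed in range(3):
            cfg = choose_implants(default_config(n_reports=n_reports, seed=seed), 10, rr)
            sigs = mine_signals(expand_events(generate_reports(cfg)))
            vals.append(evaluate_recovery(sigs, cfg).per_method["consensus"].sensitivity)
        return float(np.mean(vals))

    weak, strong = sens(20_000, 2.0), sens(20_000, 8.0)
    assert strong >= weak
    small, large = sens(5_000, 4.0), sens(40_000, 4.0)
    assert large >= small
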