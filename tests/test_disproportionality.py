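import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pvkit.data_model import DrugDictionary, DrugEventCombination
from pvkit.disproportionality import (
    DEFAULT_CRITERIA,
    FourfoldTable,
    SignalCriteria,
    build_fourfold,
    mhra_flag,
    mine_signals,
    off_label_flags,
    prr_stats,
    ror_stats,
    signals_to_frame,
    yates_chi2,
)
from pvkit import fixtures

T = FourfoldTable(10, 90, 100, 9900)


def test_build_fourfold_direct_count():
    events = (
        [DrugEventCombination(f"r{i}", "D1", "rash") for i in range(3)]
        + [DrugEventCombination(f"s{i}", "D1", "nausea") for i in range(2)]
        + [DrugEventCombination("t0", "D2", "rash")]
        + [DrugEventCombination(f"u{i}", "D2", "nausea") for i in range(4)]
    )
    t = build_fourfold(events, "D1", "rash")
    assert (t.a, t.b, t.c, t.d) == (3, 2, 1, 4)
    assert t.n == 10


def test_build_fourfold_absent_drug():
    events = [DrugEventCombination("r1", "D1", "rash")]
    t = build_fourfold(events, "D9", "rash")
    assert t.a == 0 and t.b == 0


def test_build_fourfold_empty_background():
    with pytest.raises(ValueError, match="empty"):
        build_fourfold([], "D1", "rash")


def test_fourfold_margins_match_on_random_event_sets():
    rng = np.random.default_rng(5)
    drugs = [f"D{i}" for i in range(4)]
    adrs = [f"A{i}" for i in range(5)]
    events = [
        DrugEventCombination(f"r{i}", drugs[rng.integers(4)], adrs[rng.integers(5)])
        for i in range(300)
    ]
    for drug in drugs:
        for adr in adrs:
            t = build_fourfold(events, drug, adr)
            # brute-force recount of the margins
            n_drug = sum(e.drug == drug for e in events)
            n_adr = sum(e.adr == adr for e in events)
            assert t.a + t.b == n_drug
            assert t.a + t.c == n_adr
            assert t.n == len(events)


def test_ror_point_estimate_and_ci():
    res = ror_stats(T)
    assert res.estimate == pytest.approx(11.00, abs=1e-9)
    assert res.ci_low == pytest.approx(5.56, abs=0.005)
    assert res.flag is True


def test_ror_no_disproportion_not_flagged():
    res = ror_stats(FourfoldTable(5, 5, 5, 5))
    assert res.estimate == pytest.approx(1.00)
    assert res.flag is False


def test_prr_point_estimate_and_ci():
    res = prr_stats(T)
    assert res.estimate == pytest.approx(10.00, abs=1e-9)
    assert res.ci_low == pytest.approx(5.38, abs=0.005)
    assert res.flag is True


def test_prr_proportional_rows_not_flagged():
    res = prr_stats(FourfoldTable(10, 90, 20, 180))  # a/(a+b) == c/(c+d)
    assert res.estimate == pytest.approx(1.00)
    assert res.flag is False


def test_zero_cell_is_undefined_never_flagged():
    t = FourfoldTable(0, 10, 5, 100)
    for fn in (ror_stats, prr_stats):
        res = fn(t)
        assert math.isnan(res.estimate) and res.flag is False
    assert not mhra_flag(t)


def test_haldane_correction_gives_finite_estimates():
    t = FourfoldTable(5, 0, 3, 100)
    assert math.isnan(ror_stats(t).estimate)
    res = ror_stats(t, haldane=True)
    assert math.isfinite(res.estimate)


def test_yates_chi2_value():
    assert yates_chi2(T) == pytest.approx(66.33, abs=0.01)


def test_yates_clamps_to_zero_near_independence():
    # |ad - bc| = |1*1 - 1*1| = 0 <= N/2
    assert yates_chi2(FourfoldTable(1, 1, 1, 1)) == 0.0


def test_yates_row_swap_symmetry():
    rng = np.random.default_rng(9)
    for _ in range(1000):
        a, b, c, d = rng.integers(1, 200, size=4)
        t1 = FourfoldTable(int(a), int(b), int(c), int(d))
        t2 = FourfoldTable(int(c), int(d), int(a), int(b))
        assert yates_chi2(t1) == pytest.approx(yates_chi2(t2), rel=1e-12)


def test_yates_matches_reference_when_correction_applies():
    rng = np.random.default_rng(10)
    checked = 0
    while checked < 200:
        a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
        n = a + b + c + d
        if abs(a * d - b * c) <= n / 2:
            continue
        ours = yates_chi2(FourfoldTable(a, b, c, d))
        ref, _, _, _ = chi2_contingency([[a, b], [c, d]], correction=True)
        assert ours == pytest.approx(ref, rel=1e-9)
        checked += 1


def test_printed_denominator_variant_differs():
    assert yates_chi2(T, printed_denominator=True) != pytest.approx(yates_chi2(T))


def test_zero_margin_chi2_nan():
    assert math.isnan(yates_chi2(FourfoldTable(0, 0, 5, 5)))


def test_mhra_count_gate():
    # huge disproportion but a = 2 fails the a >= 3 gate
    assert not mhra_flag(FourfoldTable(2, 1, 1, 10000))
    assert mhra_flag(T)
    assert not mhra_flag(FourfoldTable(10, 90, 100, 900))  # PRR = 1


cells = st.integers(1, 60)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(cells, cells, cells, cells)
def test_sign_identity_and_prr_bounded_by_ror(a, b, c, d):
    t = FourfoldTable(a, b, c, d)
    ror = ror_stats(t).estimate
    prr = prr_stats(t).estimate
    det = a * d - b * c
    assert math.copysign(1, ror - 1) == math.copysign(1, prr - 1) or det == 0
    if ror > 1:
        assert prr <= ror + 1e-12


def test_monotone_in_a_on_signal_side():
    # holding b, c, d fixed, raising a strengthens every statistic once ad >= bc
    for b, c, d in [(5, 7, 90), (2, 2, 50), (10, 1, 30)]:
        prev = (-math.inf, -math.inf, -math.inf)
        start = math.ceil(b * c / d)
        for a in range(max(1, start), start + 10):
            t = FourfoldTable(a, b, c, d)
            cur = (ror_stats(t).estimate, prr_stats(t).estimate, yates_chi2(t))
            assert all(x >= p - 1e-12 for x, p in zip(cur, prev))
            prev = cur


def _toy_events():
    rng = np.random.default_rng(0)
    drugs = ["D1", "D2", "D3"]
    adrs = ["rash", "nausea", "fever"]
    events = [
        DrugEventCombination(
            f"r{i}", drugs[rng.integers(3)], adrs[rng.choice(3, p=[0.5, 0.45, 0.05])]
        )
        for i in range(400)
    ]
    # implant a strong disproportion on the rare background term
    events += [DrugEventCombination(f"x{i}", "D1", "fever") for i in range(60)]
    return events


def test_mine_signals_finds_implanted_disproportion():
    signals = mine_signals(_toy_events())
    flagged = {(s.drug, s.adr) for s in signals if s.consensus}
    assert ("D1", "fever") in flagged


def test_mine_signals_consensus_subset_of_each_method():
    signals = mine_signals(_toy_events())
    cons = {(s.drug, s.adr) for s in signals if s.consensus}
    for attr in ("flag_ror", "flag_prr", "flag_mhra"):
        per = {(s.drug, s.adr) for s in signals if getattr(s, attr)}
        assert cons <= per


def test_mine_signals_empty_and_ordering():
    assert mine_signals([]) == []
    signals = mine_signals(_toy_events())
    keys = [(s.drug, -s.ror if not math.isnan(s.ror) else math.inf, s.adr) for s in signals]
    assert keys == sorted(keys)
    # matches one-at-a-time fourfold construction
    events = _toy_events()
    for s in signals[:5]:
        assert s.table == build_fourfold(events, s.drug, s.adr)


def test_mine_signals_report_unit_counts_distinct_reports():
    events = [
        DrugEventCombination("r1", "D1", "rash"),
        DrugEventCombination("r1", "D2", "rash"),
        DrugEventCombination("r2", "D1", "nausea"),
    ]
    by_event = {(s.drug, s.adr): s.table for s in mine_signals(events, unit="events")}
    by_report = {(s.drug, s.adr): s.table for s in mine_signals(events, unit="reports")}
    assert by_event[("D1", "rash")].n == 3  # three events
    assert by_report[("D1", "rash")].n == 2  # two distinct reports


def test_off_label_flags_against_published_annotations():
    label_map = fixtures.signal_derived_label_map()
    ddict = DrugDictionary(synonym_map={}).with_labels(label_map)
    events = (
        [DrugEventCombination(f"r{i}", "Ceftezole", "tremor") for i in range(5)]
        + [DrugEventCombination(f"s{i}", "Ceftezole", "rash") for i in range(5)]
        + [DrugEventCombination(f"t{i}", "Mystery drug", "rash") for i in range(5)]
        + [DrugEventCombination(f"u{i}", "Other", "other adr") for i in range(30)]
    )
    flagged = {(s.drug, s.adr): s.off_label for s in off_label_flags(mine_signals(events), ddict)}
    assert flagged[("Ceftezole", "tremor")] is True
    assert flagged[("Ceftezole", "rash")] is False
    assert flagged[("Mystery drug", "rash")] is None


def test_criteria_validation_and_frame_round():
    with pytest.raises(ValueError):
        SignalCriteria(min_a=0)
    df = signals_to_frame(mine_signals(_toy_events()))
    assert {"drug", "adr", "ror", "consensus"} <= set(df.columns)
    assert len(df) > 0
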