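"""PPV estimation, Wald intervals, interval-floor curves, rule derivation."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from sadedup.stats import (
    PPVEstimate,
    RuleSpec,
    derive_rule,
    interval_bin_label,
    interval_floor_curve,
    method_cross_table,
    ppv_by_interval_bin,
    ppv_by_method,
    ppv_by_setting,
    round_half_up,
    wald_ci,
)


def test_wald_ci_matches_statsmodels_on_interior_cases():
    """On proportions away from the boundary the unclipped Wald interval
    coincides with the standard normal-approximation interval (using the
    exact normal quantile instead of the tables' rounded z = 1.96)."""
    from scipy.stats import norm

    for k, n in [(134, 274), (180, 1015), (19, 48), (52, 249)]:
        low, high = wald_ci(k, n, z=float(norm.ppf(0.975)))
        sm_low, sm_high = proportion_confint(k, n, alpha=0.05, method="normal")
        assert low == pytest.approx(sm_low, abs=1e-10)
        assert high == pytest.approx(sm_high, abs=1e-10)


def test_wald_ci_is_unclipped_near_boundary():
    low, high = wald_ci(22, 23)
    assert high > 1.0
    assert wald_ci(0, 10) == (0.0, 0.0)


def test_wald_ci_errors():
    with pytest.raises(ValueError, match="n = 0"):
        wald_ci(0, 0)
    with pytest.raises(ValueError):
        wald_ci(5, 3)


def test_ppv_estimate_undefined_for_empty_stratum():
    est = PPVEstimate.from_counts(0, 0)
    assert not est.defined
    assert np.isnan(est.ppv) and np.isnan(est.ci_low)
    est = PPVEstimate.from_counts(3, 4)
    assert est.ci_low <= est.ppv <= est.ci_high


def test_round_half_up():
    assert round_half_up(0.145, 2) == 0.15
    assert round_half_up(0.955, 2) == 0.96
    assert round_half_up(82.2660, 1) == 82.3
    assert np.isnan(round_half_up(float("nan")))


def test_ppv_by_setting_strata_and_overall(pair_table):
    pairs = pair_table(
        [(1, False, False, True, False)] * 9 + [(2, False, False, True, True)]
        + [(1, True, False, True, False)] * 4 + [(10, True, False, True, True)]
        + [(30, False, True, True, True)] * 3
        + [(3, True, True, True, False), (40, True, True, True, True)]
    )
    tbl = ppv_by_setting(pairs).set_index("stratum")
    assert tbl.loc["nonED_nonED", "n_pairs"] == 10
    assert tbl.loc["nonED_nonED", "ppv"] == pytest.approx(0.1)
    assert tbl.loc["nonED_ED", "ppv"] == pytest.approx(1.0)
    assert tbl["n_pairs"].drop("overall").sum() == tbl.loc["overall", "n_pairs"]
    assert tbl.loc["overall", "interval_median"] == pairs["interval_days"].median()


def test_ppv_by_setting_reports_empty_stratum(pair_table):
    pairs = pair_table([(1, False, False, True, False)] * 3)
    tbl = ppv_by_setting(pairs).set_index("stratum")
    assert tbl.loc["ED_ED", "n_pairs"] == 0
    assert np.isnan(tbl.loc["ED_ED", "ppv"])


def test_ppv_requires_labels(pair_table):
    pairs = pair_table([(1, False, False, True, False)])
    pairs.loc[0, "distinct_label"] = pd.NA
    with pytest.raises(ValueError, match="missing distinct labels"):
        ppv_by_setting(pairs)


def test_ppv_by_method(pair_table):
    pairs = pair_table(
        [(1, False, False, True, False)] * 5 + [(9, False, False, True, True)]
        + [(1, False, False, False, False)] * 3 + [(9, False, False, False, True)]
    )
    tbl = ppv_by_method(pairs).set_index("stratum")
    assert tbl.loc["same_method", "n_pairs"] == 6
    assert tbl.loc["same_method", "ppv"] == pytest.approx(1 / 6)
    assert tbl.loc["different_method", "ppv"] == pytest.approx(0.25)


def test_method_cross_table_priority_tiebreak(pair_table):
    pairs = pair_table([(1, False, False, True, False)])
    # a day carrying both a specific method and 'other' counts as the
    # specific method (priority order, 'other' last)
    pairs.at[0, "first_methods"] = frozenset({"other", "poisoning"})
    pairs.at[0, "second_methods"] = frozenset({"cutting_piercing", "firearm"})
    tbl = method_cross_table(pairs)
    assert tbl.iloc[0]["first_method"] == "poisoning"
    assert tbl.iloc[0]["second_method"] == "cutting_piercing"


def test_interval_bin_edges():
    assert interval_bin_label(1) == "1-7"
    assert interval_bin_label(7) == "1-7"
    assert interval_bin_label(8) == "8-14"
    assert interval_bin_label(91) == "85-91"
    assert interval_bin_label(92) == "92+"
    assert interval_bin_label(400) == "92+"


def test_ppv_by_interval_bin_counts_sum(pair_table):
    rows = [(d, False, False, True, d > 20) for d in (1, 7, 8, 14, 15, 91, 92, 400)]
    tbl = ppv_by_interval_bin(pair_table(rows)).set_index("stratum")
    assert tbl.loc["1-7", "n_pairs"] == 2
    assert tbl.loc["92+", "n_pairs"] == 2
    assert tbl["n_pairs"].drop("overall").sum() == tbl.loc["overall", "n_pairs"]


def test_interval_floor_curve_properties(pair_table):
    d_star = 4
    rows = [(d, True, True, True, d >= d_star) for d in range(1, 9) for _ in range(3)]
    pairs = pair_table(rows)
    curve = interval_floor_curve(pairs, "all")
    assert curve["floor"].iloc[0] == 1
    assert curve["n"].iloc[0] == len(pairs)  # floor 1 covers every pair
    overall = pairs["distinct_label"].astype(bool).mean()
    assert curve["ppv"].iloc[0] == pytest.approx(overall)
    assert (np.diff(curve["n"]) <= 0).all()  # n non-increasing in the floor
    hits = curve[curve["ppv"] >= 1.0]
    assert hits["floor"].iloc[0] == d_star    # curve hits 1.0 exactly at d*


def test_derive_rule_on_ed_floor_fixture(ed_floor5_pairs):
    rule, report = derive_rule(ed_floor5_pairs, benchmark=0.90)
    assert rule.ed_floor_days == 5
    report = report.set_index("stratum")
    assert report.loc["second_ED", "floor_days"] == 5
    # at a 4-day floor the ED stratum PPV is 20/25 = 0.80, below benchmark
    curve = interval_floor_curve(ed_floor5_pairs, "second_ED").set_index("floor")
    assert curve.loc[4, "ppv"] == pytest.approx(0.80)


def test_derive_rule_degenerate_benchmarks(pair_table):
    mixed = pair_table([(d, True, True, True, d == 1) for d in (1, 2, 3)])
    rule, _ = derive_rule(mixed, benchmark=1e-9)
    assert rule.ed_floor_days == 1  # any stratum with a distinct pair qualifies at floor 1
    pairs = pair_table([(d, True, True, True, False) for d in (1, 2, 3)])
    rule, report = derive_rule(pairs, benchmark=0.90)
    assert rule.ed_floor_days is None  # all labels false: floor absent
    assert report.set_index("stratum")["floor_days"].isna().all()


def test_derive_rule_monotone_in_benchmark(cohort_pairs):
    floors = []
    for benchmark in (0.5, 0.7, 0.9):
        rule, report = derive_rule(cohort_pairs, benchmark=benchmark,
                                   include_global_floor=True)
        floors.append((rule.ed_floor_days, rule.global_floor_days))
    for (ed_a, gl_a), (ed_b, gl_b) in zip(floors, floors[1:]):
        assert ed_a <= ed_b and gl_a <= gl_b


def test_derive_rule_strict_mode(pair_table):
    # PPV crosses the benchmark at floor 2, dips at floor 3, recovers at 4
    rows = ([(1, True, True, True, False)] * 10
            + [(2, True, True, True, True)] * 40
            + [(3, True, True, True, False)] * 5 + [(3, True, True, True, True)]
            + [(4, True, True, True, True)] * 9)
    pairs = pair_table(rows)
    loose, _ = derive_rule(pairs, benchmark=0.90)
    strict, _ = derive_rule(pairs, benchmark=0.90, strict=True)
    assert loose.ed_floor_days == 2
    assert strict.ed_floor_days == 4


def test_rule_spec_validation_and_roundtrip(tmp_path):
    with pytest.raises(ValueError, match="benchmark"):
        RuleSpec(benchmark=0.0)
    with pytest.raises(ValueError, match="ed_floor_days"):
        RuleSpec(ed_floor_days=0)
    with pytest.raises(ValueError, match="index_event_policy"):
        RuleSpec(index_event_policy="flip_a_coin")
    rule = RuleSpec.permissive()
    path = tmp_path / "rule.json"
    rule.to_json(str(path))
    assert RuleSpec.from_json(str(path)) == rule
    assert RuleSpec.default().ed_floor_days == 5
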