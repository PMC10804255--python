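"""Encounter ingestion, day aggregation, pairing, frames and filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_pairs, random_small_events
from sadedup.events import (
    ReaderConfig,
    aggregate_days,
    build_pairs,
    events_from_frame,
    filter_contiguous_inpatient,
    filter_icd9_pairs,
    filter_to_frame,
    read_encounters,
    sampling_frame,
)


def _write_csv(path, rows, header="patient_id,encounter_id,date,icd_code,icd_version,setting"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return str(path)


def test_read_encounters_filters_and_maps_settings(tmp_path):
    path = _write_csv(tmp_path / "enc.csv", [
        "P1,E1,2020-05-01,T43.012A,10,ER",
        "P1,E2,2020-05-01,Z91.51,10,OUTPATIENT",       # fails case definition
        "P1,E3,2020-05-03,X78.0XXA,10,INPATIENT",
        "P2,E4,2020-05-01,E950.0,9,ICU",
    ])
    events = read_encounters(path, ReaderConfig(setting_map={"ER": "ED"}))
    assert len(events) == 3
    assert events.loc[events["encounter_id"] == "E1", "setting"].item() == "ED"
    assert set(events["method"]) == {"poisoning", "cutting_piercing"}


def test_read_encounters_custom_columns(tmp_path):
    path = _write_csv(tmp_path / "enc.csv",
                      ["P1,V1,2020-01-01,T43.012A,10,EMERGENCY"],
                      header="mrn,visit,svc_date,dx,dx_ver,dept")
    cfg = ReaderConfig(columns={"patient_id": "mrn", "encounter_id": "visit",
                                "date": "svc_date", "icd_code": "dx",
                                "icd_version": "dx_ver", "setting": "dept"})
    events = read_encounters(path, cfg)
    assert list(events["patient_id"]) == ["P1"]


def test_read_encounters_bad_rows_raise_or_skip(tmp_path):
    rows = [
        "P1,E1,2020-05-01,T43.012A,10,EMERGENCY",
        "P1,E2,not-a-date,T43.012A,10,EMERGENCY",
        "P1,E3,2020-05-02,T43.012A,10,TELEPORTER",
        "P1,E4,2020-05-03,T43.012A,11,EMERGENCY",
    ]
    path = _write_csv(tmp_path / "enc.csv", rows)
    with pytest.raises(ValueError) as err:
        read_encounters(path, ReaderConfig(on_error="raise"))
    msg = str(err.value)
    assert "not-a-date" in msg and "TELEPORTER" in msg and "11" in msg
    events = read_encounters(path, ReaderConfig(on_error="skip"))
    assert list(events["encounter_id"]) == ["E1"]


def test_read_encounters_empty_and_exclusions(tmp_path):
    path = _write_csv(tmp_path / "empty.csv", [])
    assert read_encounters(path).empty
    path = _write_csv(tmp_path / "enc.csv", [
        "P1,E1,2020-05-01,T43.012A,10,EMERGENCY",
        "P1,E2,2020-05-02,T43.012A,10,EMERGENCY",
    ])
    events = read_encounters(path, ReaderConfig(exclude_encounters={"E2"}))
    assert list(events["encounter_id"]) == ["E1"]


def _events(rows):
    """rows: (patient, date, setting, method, version[, code])"""
    recs = []
    for i, row in enumerate(rows):
        pid, date, setting, method, version = row[:5]
        recs.append({"patient_id": pid, "encounter_id": f"E{i}",
                     "date": pd.Timestamp(date), "code": row[5] if len(row) > 5 else "T39.012A",
                     "code_norm": "X", "version": version, "setting": setting,
                     "method": method, "subsequent": False})
    return pd.DataFrame(recs)


def test_aggregate_days_union_rule():
    days = aggregate_days(_events([
        ("P1", "2020-05-01", "ED", "poisoning", 10),
        ("P1", "2020-05-01", "inpatient", "other", 9),
        ("P2", "2020-05-01", "outpatient", "cutting_piercing", 10),
    ]))
    assert len(days) == 2
    day = days[days["patient_id"] == "P1"].iloc[0]
    assert day["ed_flag"] and day["settings"] == {"ED", "inpatient"}
    assert day["methods"] == {"poisoning", "other"} and day["versions"] == {9, 10}
    assert not days[days["patient_id"] == "P2"]["ed_flag"].item()


def test_aggregate_days_idempotent(cohort_days):
    again = aggregate_days(cohort_days)
    pd.testing.assert_frame_equal(again, cohort_days)


def test_build_pairs_intervals_and_methods():
    days = aggregate_days(_events([
        ("P1", "2020-01-01", "ED", "poisoning", 10),
        ("P1", "2020-01-02", "inpatient", "poisoning", 10),
        ("P1", "2020-03-15", "ED", "other", 10),
    ]))
    pairs = build_pairs(days)
    assert list(pairs["interval_days"]) == [1, 73]
    assert list(pairs["setting_type"]) == ["ED_nonED", "nonED_ED"]
    assert list(pairs["same_method"]) == [True, False]
    assert build_pairs(days.iloc[:1]).empty


def test_build_pairs_same_method_is_set_intersection():
    days = aggregate_days(_events([
        ("P1", "2020-01-01", "ED", "poisoning", 10),
        ("P1", "2020-01-02", "inpatient", "poisoning", 10),
        ("P1", "2020-01-02", "inpatient", "other", 10),
    ]))
    pairs = build_pairs(days)
    assert pairs["same_method"].item()  # {poisoning} & {poisoning, other}


def test_build_pairs_matches_bruteforce_small():
    rng = np.random.default_rng(7)
    events = random_small_events(rng, 50)
    pairs = build_pairs(aggregate_days(events))
    got = list(zip(pairs["patient_id"], pairs["first_date"], pairs["second_date"],
                   pairs["interval_days"]))
    assert sorted(got) == sorted(brute_force_pairs(events))


def test_sampling_frames():
    days = aggregate_days(_events([
        ("P1", "2020-01-01", "ED", "poisoning", 10),     # single pair, 120 d
        ("P1", "2020-04-30", "ED", "poisoning", 10),
        ("P2", "2020-01-01", "ED", "poisoning", 10),     # pairs at 30 and 200 d
        ("P2", "2020-01-31", "ED", "poisoning", 10),
        ("P2", "2020-08-18", "ED", "poisoning", 10),
        ("P3", "2020-01-01", "ED", "poisoning", 10),     # one code only
    ]))
    assert list(sampling_frame(days, "narrow")) == ["P2"]
    assert list(sampling_frame(days, "broad")) == ["P1", "P2"]
    pairs = build_pairs(days)
    narrow = filter_to_frame(pairs, "narrow")
    # all of P2's pairs are retained, including the >90-day one
    assert sorted(narrow["interval_days"]) == [30, 200]
    with pytest.raises(ValueError, match="unknown sampling frame"):
        sampling_frame(days, "medium")


def test_contiguous_inpatient_filter():
    days = aggregate_days(_events([
        ("P1", "2020-05-01", "inpatient", "poisoning", 10),
        ("P1", "2020-05-02", "inpatient", "poisoning", 10),
        ("P1", "2020-05-03", "icu", "poisoning", 10),
        ("P2", "2020-05-01", "ED", "poisoning", 10),
        ("P2", "2020-05-02", "inpatient", "poisoning", 10),
    ]))
    kept = filter_contiguous_inpatient(days)
    p1 = kept[kept["patient_id"] == "P1"]
    assert list(p1["date"].dt.day) == [1]            # only day 1 of the run
    assert len(kept[kept["patient_id"] == "P2"]) == 2  # prior day was ED


def test_contiguous_inpatient_filter_never_drops_ed_days(cohort_days):
    kept = filter_contiguous_inpatient(cohort_days)
    n_ed_before = int(cohort_days["ed_flag"].sum())
    n_ed_after = int(kept["ed_flag"].sum())
    assert n_ed_after == n_ed_before


def test_filter_icd9_pairs():
    days = aggregate_days(_events([
        ("P1", "2020-01-01", "ED", "poisoning", 9),
        ("P1", "2020-01-02", "ED", "poisoning", 10),
        ("P1", "2020-01-05", "ED", "poisoning", 10),
    ]))
    pairs = build_pairs(days)
    kept = filter_icd9_pairs(pairs)
    assert len(pairs) == 2 and len(kept) == 1
    assert kept["interval_days"].item() == 3
    assert filter_icd9_pairs(pairs.iloc[0:0]).empty


def test_setting_partition_sums_to_total(cohort_pairs):
    counts = cohort_pairs["setting_type"].value_counts()
    assert counts.sum() == len(cohort_pairs)
    assert set(counts.index) <= {"nonED_nonED", "ED_nonED", "nonED_ED", "ED_ED"}
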