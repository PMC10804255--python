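import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sadedup.events import aggregate_days, build_pairs, events_from_frame, filter_to_frame
from sadedup.synth import SimConfig, label_pairs, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _pair_table(rows):
    """Build a labeled pair table from (interval, first_ed, second_ed,
    same_method, distinct) tuples; methods/versions filled with neutral
    values."""
    base = pd.Timestamp("2020-01-01")
    recs = []
    for i, (interval, first_ed, second_ed, same_method, distinct) in enumerate(rows):
        recs.append({
            "patient_id": f"P{i:04d}",
            "first_date": base,
            "second_date": base + pd.Timedelta(days=interval),
            "interval_days": int(interval),
            "first_ed": bool(first_ed),
            "second_ed": bool(second_ed),
            "setting_type": ("ED" if first_ed else "nonED") + "_" + ("ED" if second_ed else "nonED"),
            "first_methods": frozenset({"poisoning"}),
            "second_methods": frozenset({"poisoning"} if same_method else {"other"}),
            "same_method": bool(same_method),
            "has_icd9": False,
            "second_subsequent": False,
            "distinct_label": bool(distinct),
        })
    out = pd.DataFrame(recs)
    out["distinct_label"] = out["distinct_label"].astype("boolean")
    return out


@pytest.fixture
def pair_table():
    return _pair_table


@pytest.fixture
def ed_floor5_pairs():
    """Second-code-ED pairs distinct iff interval >= 5 (plus non-ED filler).

    Below a 5-day floor the ED stratum's PPV stays under 0.90 (at floor 4
    it is 20/25 = 0.80), and at 5 days it is 1.0, so the derived ED floor
    is exactly 5.
    """
    rows = []
    for interval in range(1, 9):
        for _ in range(5):
            rows.append((interval, True, True, True, interval >= 5))
    for interval in (1, 1, 2, 3):  # non-ED leaked filler
        rows.append((interval, False, False, True, False))
    return _pair_table(rows)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_patients=2000, seed=91625)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def cohort_days(cohort):
    encounters, _ = cohort
    return aggregate_days(events_from_frame(encounters))


@pytest.fixture(scope="session")
def cohort_pairs(cohort, cohort_days):
    _, truth = cohort
    pairs = filter_to_frame(build_pairs(cohort_days), "narrow")
    return label_pairs(pairs, truth)


def random_small_events(rng, n_patients):
    """Random encounter-level frame for brute-force pairing checks."""
    rows = []
    base = pd.Timestamp("2019-06-01")
    settings_pool = ["ED", "inpatient", "icu", "outpatient", "other_unclear"]
    for p in range(n_patients):
        n = int(rng.integers(1, 21))
        days = rng.integers(0, 100, size=n)
        for k, day in enumerate(days):
            rows.append({
                "patient_id": f"R{p:04d}",
                "encounter_id": f"R{p:04d}-{k}",
                "date": base + pd.Timedelta(days=int(day)),
                "code": "T39.012A",
                "code_norm": "T39012A",
                "version": 10,
                "setting": settings_pool[int(rng.integers(5))],
                "method": "poisoning",
                "subsequent": False,
            })
    return pd.DataFrame(rows)


def brute_force_pairs(events):
    """Oracle: sort each patient's distinct dates and pair adjacent ones."""
    out = []
    for pid, grp in events.groupby("patient_id"):
        dates = sorted(set(grp["date"]))
        for a, b in zip(dates, dates[1:]):
            out.append((pid, a, b, (b - a).days))
    return out
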