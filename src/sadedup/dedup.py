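"""Apply a derived interval-floor rule to an unlabeled day-level code stream.

Every patient-day is labelled either a distinct suicide-attempt event or a
nonindependent ("leaked") re-documentation of an earlier one.  The
interval feeding the rule is measured to the *immediately preceding*
coded day — leaked or not — matching how the rule was derived from
consecutive code pairs; a ``since_last_event`` mode measuring to the last
accepted event is available but non-default.
"""

from __future__ import annotations

import pandas as pd

from .events import aggregate_days
from .stats import RuleSpec

__all__ = ["apply_rule", "compare_label_sets", "score_against_truth", "RuleSpec"]

REASONS = ("index_event", "ed_floor_met", "global_floor_met", "leaked")


def apply_rule(
    day_events: pd.DataFrame,
    rule: RuleSpec,
    interval_reference: str = "preceding_code",
) -> pd.DataFrame:
    """Label each patient-day distinct/leaked under an interval-floor rule.

    Parameters
    ----------
    day_events
        Day-aggregated frame (one row per patient-day, dates non-decreasing
        within patient); an encounter-level frame is aggregated first.
    rule
        The floors and index-event policy to apply.
    interval_reference
        ``"preceding_code"`` (default) measures the interval to the
        immediately preceding coded day; ``"since_last_event"`` to the most
        recent day already accepted as an event.

    Returns
    -------
    DataFrame with columns ``patient_id, date, ed_flag, is_distinct_event,
    event_index, reason``; ``event_index`` is consecutive from 1 within
    each patient and missing for leaked days.
    """
    if interval_reference not in ("preceding_code", "since_last_event"):
        raise ValueError(f"unknown interval_reference {interval_reference!r}")
    has_floor = rule.ed_floor_days is not None or rule.global_floor_days is not None
    if rule.index_event_policy == "first_code_ignored" and not has_floor:
        raise ValueError("rule with no floors and first_code_ignored can never fire")

    cols = ["patient_id", "date", "ed_flag", "is_distinct_event", "event_index", "reason"]
    d = day_events if "settings" in getattr(day_events, "columns", ()) else aggregate_days(day_events)
    if d.empty:
        out = pd.DataFrame(columns=cols)
        return out.astype({"event_index": "Int64"}, errors="ignore")

    # reject unsorted / duplicated patient-days rather than silently fixing
    for pid, grp in d.groupby("patient_id", sort=False):
        dates = grp["date"].to_numpy()
        if len(dates) > 1 and not (dates[1:] > dates[:-1]).all():
            raise ValueError(f"day events for patient {pid!r} are not strictly date-sorted")

    rows = []
    for pid, grp in d.groupby("patient_id", sort=False):
        prev_date = None
        last_event_date = None
        event_index = 0
        for date, ed_flag in zip(grp["date"], grp["ed_flag"]):
            if prev_date is None:
                if rule.index_event_policy == "first_code_is_event":
                    reason = "index_event"
                else:
                    reason = "leaked"
            else:
                ref = prev_date if interval_reference == "preceding_code" else (
                    last_event_date if last_event_date is not None else prev_date
                )
                interval = (date - ref).days
                if rule.ed_floor_days is not None and ed_flag and interval >= rule.ed_floor_days:
                    reason = "ed_floor_met"
                elif rule.global_floor_days is not None and interval >= rule.global_floor_days:
                    reason = "global_floor_met"
                else:
                    reason = "leaked"
            distinct = reason != "leaked"
            if distinct:
                event_index += 1
                last_event_date = date
            rows.append({"patient_id": pid, "date": date, "ed_flag": bool(ed_flag),
                         "is_distinct_event": distinct,
                         "event_index": event_index if distinct else pd.NA,
                         "reason": reason})
            prev_date = date
    out = pd.DataFrame(rows, columns=cols)
    return out.astype({"event_index": "Int64"})


def compare_label_sets(result_a: pd.DataFrame, result_b: pd.DataFrame) -> dict:
    """Agreement summary between two rule outputs on the same day stream.

    Returns day counts, events under each rule, and the 2×2 confusion
    counts of distinct/leaked calls.
    """
    key = ["patient_id", "date"]
    a = result_a.sort_values(key).reset_index(drop=True)
    b = result_b.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not a[key].equals(b[key]):
        raise ValueError("results are not over the same day events")
    da = a["is_distinct_event"].astype(bool).to_numpy()
    db = b["is_distinct_event"].astype(bool).to_numpy()
    n = len(a)
    return {
        "n_days": n,
        "events_a": int(da.sum()),
        "events_b": int(db.sum()),
        "both_distinct": int((da & db).sum()),
        "only_a": int((da & ~db).sum()),
        "only_b": int((~da & db).sum()),
        "both_leaked": int((~da & ~db).sum()),
        "agreement": float((da == db).mean()) if n else float("nan"),
    }


def score_against_truth(result: pd.DataFrame, truth_new_days: pd.DataFrame) -> dict:
    """Precision/recall of distinct-event calls against simulator ground truth.

    ``truth_new_days`` carries ``patient_id, date, is_new`` (see
    :func:`sadedup.synth.true_new_event_days`); a predicted distinct day is
    a true positive when that day really introduces a new underlying event.
    """
    merged = result.merge(truth_new_days, on=["patient_id", "date"], how="left")
    if merged["is_new"].isna().any():
        raise ValueError("truth table does not cover every labelled day")
    pred = merged["is_distinct_event"].astype(bool).to_numpy()
    true = merged["is_new"].astype(bool).to_numpy()
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    return {
        "n_days": len(merged),
        "true_positive": tp,
        "false_positive": fp,
        "false_negative": fn,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
    }
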