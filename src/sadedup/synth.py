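"""Synthetic EHR cohorts with known suicide-attempt event structure.

Real chart-reviewed encounter data cannot be shared, so this module
generates labeled cohorts that reproduce the *leakage structure* the rule
derivation depends on: each true attempt event spawns a cascade of coded
encounters — an index presentation (usually ED), an admission with daily
inpatient coding, and outpatient/other follow-up codes — all within a
configurable leakage horizon ``H`` of the event's first code.  Under the
defaults most adjacent code pairs are nonindependent and the median
intercode interval is about one day, matching the derivation cohort's
descriptives; every emitted code passes the case definition.

The generator returns two frames: an encounter table shaped exactly like
the ingestion contract of :func:`sadedup.events.read_encounters`, and a
truth table mapping every encounter to its underlying event id, from
which pair labels (:func:`label_pairs`) and per-day new-event ground
truth (:func:`true_new_event_days`) derive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import casedef

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "label_pairs",
    "true_new_event_days",
    "CODE_POOLS",
]

#: Raw code pools per (ICD version, method category).  Every entry passes
#: the case definition.  ICD-10-CM has no hanging code inside the matched
#: X71–X83 window (X70 is outside the validated set), so ICD-10 hanging
#: events fall back to unspecified-means codes — deliberate method
#: miscoding, as seen in real data.
CODE_POOLS: dict[tuple[int, str], tuple[str, ...]] = {
    (10, "poisoning"): ("T39.012A", "T42.4X2A", "T43.212A", "T50.902A",
                        "T36.92XA", "T51.0X2A"),
    (9, "poisoning"): ("965.00", "967.0", "969.4", "E950.0"),
    (10, "cutting_piercing"): ("X78.0XXA", "X78.9XXA", "X79.8XXA"),
    (9, "cutting_piercing"): ("881.02", "E956"),
    (10, "hanging_strangulation_suffocation"): (),
    (9, "hanging_strangulation_suffocation"): ("E953.0",),
    (10, "jumping"): ("X80.XXXA", "X81.0XXA"),
    (9, "jumping"): ("E957.1",),
    (10, "firearm"): ("X72.XXXA", "X74.8XXA"),
    (9, "firearm"): ("E955.0",),
    (10, "other"): ("T14.91XA", "X83.8XXA", "X76.XXXA"),
    (9, "other"): ("E958.8", "E958.9"),
}

_SETTING_STRINGS = {"ED": "EMERGENCY", "inpatient": "INPATIENT", "icu": "ICU",
                    "outpatient": "OUTPATIENT", "other_unclear": "OTHER"}


@dataclass
class SimConfig:
    """Cohort-generator parameters (defaults emulate the derivation cohort).

    ``p_more_attempts`` drives a geometric repeat-attempt process
    (P(k attempts) ∝ p^(k−1)); inter-attempt gaps are lognormal in days
    (median ≈ exp(``gap_log_mean``)) with a hard minimum; the cascade
    parameters control the index presentation, admission length with daily
    coding, and follow-up codes, all confined to ``leak_horizon_days`` (H)
    after the event's first code.  ``p_ed_leak`` is the small chance a
    leaked follow-up code is documented in the ED.
    """

    n_patients: int = 300
    p_more_attempts: float = 0.40
    max_attempts: int = 8
    gap_log_mean: float = float(np.log(40.0))
    gap_log_sd: float = 1.1
    min_gap_days: int = 2
    p_ed_day0: float = 0.85
    p_same_day_extra: float = 0.20
    p_admit: float = 0.40
    p_icu_given_admit: float = 0.30
    los_mean_days: float = 3.5
    p_daily_code: float = 0.90
    followup_mean: float = 0.5
    followup_gap_p: float = 0.15
    p_ed_repeat: float = 0.18
    ed_repeat_gap_p: float = 0.45
    leak_horizon_days: int = 28
    p_ed_leak: float = 0.03
    p_unspecified_code: float = 0.15
    p_subsequent_flag: float = 0.25
    icd9_frac: float = 0.12
    method_probs: dict = field(default_factory=lambda: {
        "poisoning": 0.55, "cutting_piercing": 0.20, "other": 0.10,
        "firearm": 0.06, "hanging_strangulation_suffocation": 0.05,
        "jumping": 0.04,
    })
    start_date: str = "2016-01-01"
    start_window_days: int = 1460
    seed: int = 0

    def validate(self) -> None:
        probs = {k: getattr(self, k) for k in
                 ("p_more_attempts", "p_ed_day0", "p_same_day_extra", "p_admit",
                  "p_icu_given_admit", "p_daily_code", "followup_gap_p",
                  "p_ed_leak", "p_unspecified_code", "p_subsequent_flag",
                  "icd9_frac", "p_ed_repeat", "ed_repeat_gap_p")}
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.followup_gap_p == 0 and self.followup_mean > 0:
            raise ValueError("followup_gap_p must be > 0 when follow-ups occur")
        if self.ed_repeat_gap_p == 0 and self.p_ed_repeat > 0:
            raise ValueError("ed_repeat_gap_p must be > 0 when ED re-presentations occur")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.leak_horizon_days < 1:
            raise ValueError("leak_horizon_days must be >= 1")
        if self.min_gap_days < 1:
            raise ValueError("min_gap_days must be >= 1")
        if self.los_mean_days < 1 or self.followup_mean < 0:
            raise ValueError("invalid cascade length parameters")
        if abs(sum(self.method_probs.values()) - 1.0) > 1e-9:
            raise ValueError("method_probs must sum to 1")
        for m in self.method_probs:
            if m not in casedef.METHOD_CATEGORIES:
                raise ValueError(f"unknown method category {m!r}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _pick_code(rng: np.random.Generator, method: str, is_followup: bool,
               cfg: SimConfig) -> tuple[str, int]:
    version = 9 if rng.random() < cfg.icd9_frac else 10
    if rng.random() < cfg.p_unspecified_code:
        method = "other"
    pool = CODE_POOLS[(version, method)] or CODE_POOLS[(version, "other")]
    raw = pool[rng.integers(len(pool))]
    if (version == 10 and is_followup and raw.endswith("A")
            and rng.random() < cfg.p_subsequent_flag):
        raw = raw[:-1] + "D"
    return raw, version


def simulate_cohort(
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
    n_patients: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (encounter table, truth table) for a synthetic cohort.

    Reproducible: a given config (including its seed) yields byte-identical
    frames.  ``seed``/``n_patients`` override the config fields.

    Returns
    -------
    encounters : DataFrame
        ``patient_id, encounter_id, date, icd_code, icd_version, setting``
        (setting as warehouse-style strings, e.g. ``"EMERGENCY"``).
    truth : DataFrame
        ``encounter_id, patient_id, date, event_id, true_method`` — one row
        per encounter, linking it to its underlying attempt event.
    """
    cfg = config or SimConfig()
    if seed is not None or n_patients is not None:
        cfg = cfg.replace(**{k: v for k, v in
                             (("seed", seed), ("n_patients", n_patients))
                             if v is not None})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    methods = sorted(cfg.method_probs)
    method_p = np.array([cfg.method_probs[m] for m in methods])
    start = pd.Timestamp(cfg.start_date)
    horizon = cfg.leak_horizon_days

    rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:05d}"
        t = start + pd.Timedelta(days=int(rng.integers(cfg.start_window_days)))
        n_attempts = 1
        while n_attempts < cfg.max_attempts and rng.random() < cfg.p_more_attempts:
            n_attempts += 1
        for j in range(n_attempts):
            if j > 0:
                gap = max(cfg.min_gap_days,
                          int(round(rng.lognormal(cfg.gap_log_mean, cfg.gap_log_sd))))
                t = t + pd.Timedelta(days=gap)
            event_id = f"{pid}-ev{j + 1}"
            method = methods[int(rng.choice(len(methods), p=method_p))]
            encounters: list[tuple[int, str, bool]] = []  # (day offset, setting, followup?)
            ed_index = rng.random() < cfg.p_ed_day0
            day0_setting = "ED" if ed_index else (
                ("inpatient", "outpatient", "other_unclear")[
                    int(rng.choice(3, p=[0.5, 0.25, 0.25]))]
            )
            encounters.append((0, day0_setting, False))
            if rng.random() < cfg.p_same_day_extra:
                extra = "inpatient" if day0_setting == "ED" else "other_unclear"
                encounters.append((0, extra, False))
            los = 0
            if rng.random() < cfg.p_admit:
                los = 1 + int(rng.poisson(cfg.los_mean_days - 1))
                icu = rng.random() < cfg.p_icu_given_admit
                icu_days = min(2, los) if icu else 0
                for day in range(1, min(los, horizon) + 1):
                    if rng.random() < cfg.p_daily_code:
                        setting = "icu" if day <= icu_days else "inpatient"
                        encounters.append((day, setting, True))
            if rng.random() < cfg.p_ed_repeat:
                # leaked ED re-presentation shortly after the index visit
                # (transfer, return visit for the same attempt)
                offset = min(horizon, 1 + int(rng.geometric(cfg.ed_repeat_gap_p) - 1))
                encounters.append((max(1, offset), "ED", True))
            n_follow = int(rng.poisson(cfg.followup_mean))
            for _ in range(n_follow):
                offset = min(horizon,
                             min(los, horizon) + int(rng.geometric(cfg.followup_gap_p)))
                if rng.random() < cfg.p_ed_leak:
                    setting = "ED"
                else:
                    setting = ("outpatient", "other_unclear", "inpatient")[
                        int(rng.choice(3, p=[0.55, 0.30, 0.15]))]
                encounters.append((offset, setting, True))
            for offset, setting, is_followup in encounters:
                raw, version = _pick_code(rng, method, is_followup, cfg)
                rows.append({
                    "patient_id": pid,
                    "date": t + pd.Timedelta(days=offset),
                    "icd_code": raw,
                    "icd_version": version,
                    "setting": _SETTING_STRINGS[setting],
                    "event_id": event_id,
                    "true_method": method,
                })

    frame = pd.DataFrame(rows).sort_values(
        ["patient_id", "date", "setting", "icd_code"], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(1, "encounter_id", [f"E{k + 1:06d}" for k in range(len(frame))])
    encounters_out = frame[["patient_id", "encounter_id", "date", "icd_code",
                            "icd_version", "setting"]].copy()
    encounters_out["date"] = encounters_out["date"].dt.strftime("%Y-%m-%d")
    truth = frame[["encounter_id", "patient_id", "date", "event_id", "true_method"]].copy()
    return encounters_out, truth


def _day_event_sets(truth: pd.DataFrame) -> dict[tuple[str, pd.Timestamp], frozenset]:
    t = truth.copy()
    t["date"] = pd.to_datetime(t["date"]).dt.normalize()
    grouped = t.groupby(["patient_id", "date"])["event_id"].agg(frozenset)
    return dict(grouped.items())


def label_pairs(pairs: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Fill ``distinct_label`` from the simulator truth table.

    A pair is truly distinct iff the event-id sets underlying its two
    patient-days are disjoint (a day mixing codes from two events is *not*
    distinct from either of them).
    """
    lookup = _day_event_sets(truth)
    labels = []
    for pid, d1, d2 in zip(pairs["patient_id"],
                           pd.to_datetime(pairs["first_date"]),
                           pd.to_datetime(pairs["second_date"])):
        try:
            s1, s2 = lookup[(pid, d1)], lookup[(pid, d2)]
        except KeyError as err:
            raise ValueError(f"day {err.args[0]!r} missing from truth table") from None
        labels.append(s1.isdisjoint(s2))
    out = pairs.copy()
    out["distinct_label"] = pd.Series(labels, index=out.index, dtype="boolean")
    return out


def true_new_event_days(truth: pd.DataFrame) -> pd.DataFrame:
    """Per patient-day ground truth: does the day introduce a new event?

    A day is a new-event day iff it is the first coded day of at least one
    of the events represented on it.  Used to audit applied rules
    (:func:`sadedup.dedup.score_against_truth`).
    """
    t = truth.copy()
    t["date"] = pd.to_datetime(t["date"]).dt.normalize()
    first_day = t.groupby(["patient_id", "event_id"])["date"].transform("min")
    t["introduces"] = t["date"] == first_day
    out = (t.groupby(["patient_id", "date"])["introduces"].any()
           .rename("is_new").reset_index())
    return out
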