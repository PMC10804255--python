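"""Encounter-table ingestion, day-level aggregation and code-pair construction.

The longitudinal unit of analysis is the *code pair*: a suicide-attempt
coded patient-day together with the immediately preceding suicide-attempt
coded day in the same patient's record.  Because a single presentation
typically spawns a cascade of coded encounters (ED visit, admission with
daily inpatient coding, outpatient follow-up), most adjacent code pairs
re-document one underlying event; the pair table built here is what the
PPV and interval-floor machinery in :mod:`sadedup.stats` consumes.

All tabular data are plain :class:`pandas.DataFrame` objects:

``events``      one row per suicide-attempt coded encounter
                (``patient_id, encounter_id, date, code, code_norm,
                version, setting, method, subsequent``);
``day_events``  one row per patient-day (``patient_id, date, ed_flag,
                settings, methods, versions, codes, n_codes,
                subsequent_any``), sets stored as frozensets;
``pairs``       one row per consecutive patient-day pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import casedef

__all__ = [
    "SETTINGS",
    "DEFAULT_SETTING_MAP",
    "ReaderConfig",
    "read_encounters",
    "events_from_frame",
    "aggregate_days",
    "build_pairs",
    "sampling_frame",
    "filter_to_frame",
    "filter_contiguous_inpatient",
    "filter_icd9_pairs",
]

logger = logging.getLogger("sadedup")

SETTINGS = ("ED", "inpatient", "icu", "outpatient", "other_unclear")

#: Default clinical-setting string mapping (keys compared upper-cased).
DEFAULT_SETTING_MAP = {
    "ED": "ED",
    "ER": "ED",
    "EMERGENCY": "ED",
    "EMERGENCY DEPARTMENT": "ED",
    "EMERGENCY ROOM": "ED",
    "INPATIENT": "inpatient",
    "IP": "inpatient",
    "HOSPITAL": "inpatient",
    "ICU": "icu",
    "INTENSIVE CARE": "icu",
    "CRITICAL CARE": "icu",
    "OUTPATIENT": "outpatient",
    "OP": "outpatient",
    "AMBULATORY": "outpatient",
    "CLINIC": "outpatient",
    "OTHER": "other_unclear",
    "UNKNOWN": "other_unclear",
    "UNCLEAR": "other_unclear",
}

_CANONICAL_COLUMNS = ("patient_id", "encounter_id", "date", "icd_code", "icd_version", "setting")

_INPATIENT_LIKE = frozenset({"inpatient", "icu"})


@dataclass
class ReaderConfig:
    """How to read a delimited encounter table.

    ``columns`` maps canonical names to the file's header names;
    ``setting_map`` maps raw setting strings (upper-cased) to one of
    :data:`SETTINGS`; ``on_error`` is ``"raise"`` (default) or ``"skip"``
    for rows with unparseable dates, unknown settings or bad versions;
    ``exclude_encounters`` is a row-level exclusion list of encounter ids
    (the analogue of chart-review exclusions).
    """

    columns: dict = field(default_factory=lambda: {c: c for c in _CANONICAL_COLUMNS})
    setting_map: dict = field(default_factory=lambda: dict(DEFAULT_SETTING_MAP))
    on_error: str = "raise"
    delimiter: str = ","
    method_table_path: Optional[str] = None
    exclude_encounters: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.on_error not in ("raise", "skip"):
            raise ValueError("on_error must be 'raise' or 'skip'")
        cols = {c: c for c in _CANONICAL_COLUMNS}
        cols.update(self.columns)
        self.columns = cols
        self.setting_map = {k.upper(): v for k, v in self.setting_map.items()}
        self.exclude_encounters = frozenset(self.exclude_encounters)

    @classmethod
    def from_yaml(cls, path: str) -> "ReaderConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _classify_setting(value: str, setting_map: dict) -> Optional[str]:
    key = str(value).strip().upper()
    if key in setting_map:
        return setting_map[key]
    # canonical values pass through unchanged
    for s in SETTINGS:
        if key == s.upper():
            return s
    return None


def events_from_frame(df: pd.DataFrame, config: Optional[ReaderConfig] = None) -> pd.DataFrame:
    """Validate and filter an in-memory encounter table to matched events.

    Rows whose code fails the case definition are dropped (count logged).
    Rows with unparseable dates, unknown setting strings or an ICD version
    other than 9/10 are reported per row and either abort the read or are
    skipped, per ``config.on_error``.
    """
    config = config or ReaderConfig()
    if df.empty:
        logger.warning("encounter table is empty")
        return pd.DataFrame(
            columns=["patient_id", "encounter_id", "date", "code", "code_norm",
                     "version", "setting", "method", "subsequent"]
        )
    rename = {v: k for k, v in config.columns.items()}
    missing = [v for v in config.columns.values() if v not in df.columns]
    if missing:
        raise ValueError(f"input is missing configured columns: {missing}")
    df = df.rename(columns=rename)[list(_CANONICAL_COLUMNS)].copy()

    problems: list[str] = []
    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    for idx in df.index[dates.isna()]:
        problems.append(f"row {idx}: unparseable date {df.at[idx, 'date']!r}")
    versions = pd.to_numeric(df["icd_version"], errors="coerce")
    bad_version = versions.isna() | ~versions.isin([9, 10])
    for idx in df.index[bad_version]:
        problems.append(
            f"row {idx}: unknown ICD version {df.at[idx, 'icd_version']!r} "
            f"for code {df.at[idx, 'icd_code']!r}"
        )
    settings = df["setting"].map(lambda s: _classify_setting(s, config.setting_map))
    for idx in df.index[settings.isna()]:
        problems.append(f"row {idx}: unknown setting string {df.at[idx, 'setting']!r}")

    if problems:
        if config.on_error == "raise":
            raise ValueError("bad encounter rows:\n" + "\n".join(problems))
        logger.warning("skipping %d bad rows:\n%s", len(problems), "\n".join(problems))

    ok = dates.notna() & ~bad_version & settings.notna()
    out = pd.DataFrame(
        {
            "patient_id": df.loc[ok, "patient_id"].astype(str),
            "encounter_id": df.loc[ok, "encounter_id"].astype(str),
            "date": dates[ok].dt.normalize(),
            "code": df.loc[ok, "icd_code"].astype(str),
            "version": versions[ok].astype(int),
            "setting": settings[ok],
        }
    )

    if config.exclude_encounters:
        n0 = len(out)
        out = out[~out["encounter_id"].isin(config.exclude_encounters)]
        logger.info("excluded %d rows via exclusion list", n0 - len(out))

    out["code_norm"] = out["code"].map(casedef.normalize_code)
    matched = [
        casedef.matches_case_definition(c, v)
        for c, v in zip(out["code"], out["version"])
    ]
    n_dropped = len(out) - int(np.sum(matched))
    if n_dropped:
        logger.info("dropped %d rows failing the case definition", n_dropped)
    out = out[np.asarray(matched, dtype=bool)].copy()

    table = casedef.load_method_table(config.method_table_path) if config.method_table_path else None
    out["method"] = [
        casedef.classify_method(c, v, table) for c, v in zip(out["code"], out["version"])
    ]
    out["subsequent"] = [
        casedef.flag_subsequent_encounter(c, v) for c, v in zip(out["code"], out["version"])
    ]
    out = out.sort_values(["patient_id", "date", "encounter_id"], kind="mergesort")
    return out.reset_index(drop=True)[
        ["patient_id", "encounter_id", "date", "code", "code_norm",
         "version", "setting", "method", "subsequent"]
    ]


def read_encounters(path: str, config: Optional[ReaderConfig] = None) -> pd.DataFrame:
    """Read a delimited encounter file and return the matched-event table."""
    config = config or ReaderConfig()
    try:
        df = pd.read_csv(path, sep=config.delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    return events_from_frame(df, config)


def aggregate_days(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-day encounters to one row per patient-day.

    A day with *any* ED encounter is an ED day; methods/settings/versions
    are unions over the day's codes.  Idempotent: a frame that is already
    day-level passes through (re-sorted) unchanged.
    """
    if "settings" in events.columns:  # already day-level
        return events.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    cols = ["patient_id", "date", "ed_flag", "settings", "methods",
            "versions", "codes", "n_codes", "subsequent_any"]
    if events.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (pid, date), grp in events.groupby(["patient_id", "date"], sort=True):
        settings = frozenset(grp["setting"])
        rows.append(
            {
                "patient_id": pid,
                "date": date,
                "ed_flag": "ED" in settings,
                "settings": settings,
                "methods": frozenset(grp["method"]),
                "versions": frozenset(grp["version"]),
                "codes": tuple(grp["code"]),
                "n_codes": len(grp),
                "subsequent_any": bool(grp["subsequent"].any()),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def _setting_type(first_ed: bool, second_ed: bool) -> str:
    return ("ED" if first_ed else "nonED") + "_" + ("ED" if second_ed else "nonED")


def build_pairs(day_events: pd.DataFrame) -> pd.DataFrame:
    """Pair each patient-day with the immediately preceding patient-day.

    For a patient with k day-events this yields exactly k−1 pairs; the
    intercode interval is whole calendar days (≥ 1 after day aggregation).
    ``distinct_label`` is left missing; :func:`sadedup.synth.label_pairs`
    or a chart-review label source fills it.
    """
    cols = ["patient_id", "first_date", "second_date", "interval_days",
            "first_ed", "second_ed", "setting_type", "first_methods",
            "second_methods", "same_method", "has_icd9",
            "second_subsequent", "distinct_label"]
    if day_events.empty:
        return pd.DataFrame(columns=cols)
    d = aggregate_days(day_events)
    prev = d.groupby("patient_id").shift(1)
    keep = prev["date"].notna()
    d, prev = d[keep], prev[keep]
    pairs = pd.DataFrame(
        {
            "patient_id": d["patient_id"].to_numpy(),
            "first_date": prev["date"].to_numpy(),
            "second_date": d["date"].to_numpy(),
            "interval_days": (d["date"].to_numpy() - prev["date"].to_numpy())
            .astype("timedelta64[D]").astype(int),
            "first_ed": prev["ed_flag"].astype(bool).to_numpy(),
            "second_ed": d["ed_flag"].astype(bool).to_numpy(),
            "first_methods": prev["methods"].to_numpy(),
            "second_methods": d["methods"].to_numpy(),
            "has_icd9": [9 in (a | b) for a, b in zip(prev["versions"], d["versions"])],
            "second_subsequent": d["subsequent_any"].astype(bool).to_numpy(),
        }
    )
    pairs["setting_type"] = [
        _setting_type(a, b) for a, b in zip(pairs["first_ed"], pairs["second_ed"])
    ]
    pairs["same_method"] = [
        bool(a & b) for a, b in zip(pairs["first_methods"], pairs["second_methods"])
    ]
    pairs["distinct_label"] = pd.Series(pd.NA, index=pairs.index, dtype="boolean")
    if (pairs["interval_days"] < 1).any():
        raise ValueError("duplicate patient-days: aggregate before pairing")
    return pairs.reset_index(drop=True)[cols]


def sampling_frame(day_events: pd.DataFrame, frame: str = "narrow") -> np.ndarray:
    """Patients qualifying for a sampling frame.

    ``narrow``: patients with at least one pair 1–90 days apart (the frame
    enriched for leaked codes); ``broad``: any pair ≥ 1 day apart.  For
    qualifying patients *all* pairs are retained downstream, including
    >90-day pairs in the narrow frame (see :func:`filter_to_frame`).
    """
    pairs = build_pairs(day_events)
    return _frame_patients(pairs, frame)


def _frame_patients(pairs: pd.DataFrame, frame: str) -> np.ndarray:
    if frame not in ("narrow", "broad"):
        raise ValueError(f"unknown sampling frame {frame!r}")
    if pairs.empty:
        return np.array([], dtype=object)
    qual = pairs["interval_days"] >= 1
    if frame == "narrow":
        qual &= pairs["interval_days"] <= 90
    return np.sort(pairs.loc[qual, "patient_id"].unique())


def filter_to_frame(pairs: pd.DataFrame, frame: str = "narrow") -> pd.DataFrame:
    """Keep all pairs of the patients qualifying for the frame."""
    patients = _frame_patients(pairs, frame)
    return pairs[pairs["patient_id"].isin(patients)].reset_index(drop=True)


def filter_contiguous_inpatient(day_events: pd.DataFrame) -> pd.DataFrame:
    """Drop inpatient/ICU-only days directly preceded by an inpatient/ICU day.

    Sensitivity filter for multi-day admissions coded daily: of a run of
    consecutive inpatient-coded days only the first survives.  Presence is
    assessed against the *unfiltered* input, so every later day of a run is
    removed.  Days with any ED encounter are never removed.
    """
    d = aggregate_days(day_events)
    if d.empty:
        return d
    inpatient_days = {
        (pid, date)
        for pid, date, settings in zip(d["patient_id"], d["date"], d["settings"])
        if settings & _INPATIENT_LIKE
    }
    one_day = pd.Timedelta(days=1)
    drop = [
        bool(settings) and settings <= _INPATIENT_LIKE and (pid, date - one_day) in inpatient_days
        for pid, date, settings in zip(d["patient_id"], d["date"], d["settings"])
    ]
    n_drop = int(np.sum(drop))
    if n_drop:
        logger.info("contiguous-inpatient filter removed %d day-events", n_drop)
    return d[~np.asarray(drop, dtype=bool)].reset_index(drop=True)


def filter_icd9_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop pairs in which either day carries at least one ICD-9 code."""
    if pairs.empty:
        return pairs.copy()
    out = pairs[~pairs["has_icd9"].astype(bool)].reset_index(drop=True)
    logger.info("ICD-9 exclusion removed %d pairs", len(pairs) - len(out))
    return out
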