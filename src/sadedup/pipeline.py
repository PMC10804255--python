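"""End-to-end workflows: match → aggregate → pair → estimate → derive → apply.

`run_derivation` reproduces the full derivation pipeline on a labeled
cohort (chart-review style labels via an event-id source) and writes the
report bundle: setting/method/interval PPV tables, interval-floor curves,
the derived rule as JSON, and a run log with every filter count.
`run_apply` applies a stored rule to an unlabeled cohort.  Both write a
machine-readable provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .dedup import apply_rule
from .events import (ReaderConfig, aggregate_days, build_pairs,
                     filter_contiguous_inpatient, filter_icd9_pairs,
                     filter_to_frame, read_encounters)
from .rule import IntervalFloorRule
from .stats import (RuleSpec, interval_floor_curve, method_cross_table,
                    ppv_by_interval_bin, ppv_by_method, ppv_by_setting,
                    RULE_STRATA)
from .synth import label_pairs

logger = logging.getLogger("sadedup")

__all__ = ["RunConfig", "run_derivation", "run_apply"]


@dataclass
class RunConfig:
    """Configuration of a derivation or apply run."""

    input: str = ""
    truth: Optional[str] = None
    reader: ReaderConfig = field(default_factory=ReaderConfig)
    frame: str = "narrow"
    benchmark: float = 0.90
    strict: bool = False
    use_global_floor: bool = False
    index_event_policy: str = "first_code_is_event"
    contiguous_inpatient_filter: bool = False
    exclude_icd9: bool = False
    outdir: str = "sa_dedup_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.benchmark <= 1:
            raise ValueError("benchmark must be in (0, 1]")
        if self.frame not in ("narrow", "broad"):
            raise ValueError("frame must be 'narrow' or 'broad'")
        if isinstance(self.reader, dict):
            self.reader = ReaderConfig(**self.reader)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["reader"]["exclude_encounters"] = sorted(
            payload["reader"]["exclude_encounters"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig, outdir: Path, kind: str) -> None:
    record = {"kind": kind, "package_version": __version__,
              "config_hash": config.hash(), "seed": config.seed}
    (outdir / "provenance.json").write_text(json.dumps(record, indent=2) + "\n")


def _load_labeled_pairs(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    events = read_encounters(config.input, config.reader)
    counts = {"encounters_matched": len(events)}
    days = aggregate_days(events)
    counts["patient_days"] = len(days)
    if config.contiguous_inpatient_filter:
        before = len(days)
        days = filter_contiguous_inpatient(days)
        counts["contiguous_inpatient_removed"] = before - len(days)
    pairs = build_pairs(days)
    counts["pairs_total"] = len(pairs)
    pairs = filter_to_frame(pairs, config.frame)
    counts[f"pairs_in_{config.frame}_frame"] = len(pairs)
    if config.exclude_icd9:
        before = len(pairs)
        pairs = filter_icd9_pairs(pairs)
        counts["icd9_pairs_removed"] = before - len(pairs)

    if pairs.empty:
        counts["pairs_labeled"] = 0
        return pairs, counts

    if config.truth is not None:
        truth = pd.read_csv(config.truth, dtype={"patient_id": str})
    else:
        raw = pd.read_csv(config.input, dtype=str)
        id_col = config.reader.columns["encounter_id"]
        if "event_id" not in raw.columns:
            raise ValueError(
                "no labels available: supply a truth table (--truth, as "
                "written by `sa-dedup simulate`) or an event_id column in "
                "the input"
            )
        truth = raw.rename(columns={
            config.reader.columns["patient_id"]: "patient_id",
            config.reader.columns["date"]: "date",
            id_col: "encounter_id"})[["encounter_id", "patient_id", "date", "event_id"]]
    pairs = label_pairs(pairs, truth)
    counts["pairs_labeled"] = len(pairs)
    return pairs, counts


def run_derivation(config: RunConfig) -> dict:
    """Run the derivation pipeline and write the report bundle.

    Returns a dict with the fitted estimator, the labeled pairs, the
    tables, and the paths written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, counts = _load_labeled_pairs(config)

    tables: dict[str, pd.DataFrame] = {}
    if pairs.empty:
        logger.warning("no code pairs in frame %r; writing empty tables", config.frame)
        empty = pd.DataFrame()
        tables = {"ppv_by_setting": empty, "ppv_by_method": empty,
                  "ppv_by_interval_bin": empty, "method_cross_table": empty,
                  "floor_curves": empty}
        est = None
        rule = None
    else:
        tables["ppv_by_setting"] = ppv_by_setting(pairs)
        tables["ppv_by_method"] = ppv_by_method(pairs)
        tables["ppv_by_interval_bin"] = ppv_by_interval_bin(pairs)
        tables["method_cross_table"] = method_cross_table(pairs)
        tables["floor_curves"] = pd.concat(
            [interval_floor_curve(pairs, s) for s in RULE_STRATA],
            ignore_index=True,
        )
        est = IntervalFloorRule(
            benchmark=config.benchmark, strict=config.strict,
            use_global_floor=config.use_global_floor,
            index_event_policy=config.index_event_policy,
        ).fit(pairs)
        rule = est.rule_spec_
        tables["floors"] = est.report_
        rule.to_json(str(outdir / "rule.json"))

    for name, tbl in tables.items():
        tbl.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "run_log.json").write_text(json.dumps(counts, indent=2) + "\n")
    _provenance(config, outdir, "derivation")
    logger.info("derivation bundle written to %s", outdir)
    return {"estimator": est, "rule": rule, "pairs": pairs,
            "tables": tables, "counts": counts, "outdir": outdir}


def run_apply(config: RunConfig, rule: RuleSpec) -> dict:
    """Apply a stored rule to an (unlabeled) encounter table.

    Writes ``events.csv`` (per-day distinct/leaked labels) and summary
    counts; returns them.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = read_encounters(config.input, config.reader)
    days = aggregate_days(events)
    if config.contiguous_inpatient_filter:
        days = filter_contiguous_inpatient(days)
    result = apply_rule(days, rule)
    out = result.copy()
    if len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(outdir / "events.csv", index=False)
    summary = {
        "n_patient_days": len(result),
        "n_patients": int(result["patient_id"].nunique()) if len(result) else 0,
        "n_distinct_events": int(result["is_distinct_event"].sum()) if len(result) else 0,
        "reasons": (result["reason"].value_counts().to_dict() if len(result) else {}),
    }
    (outdir / "apply_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _provenance(config, outdir, "apply")
    return {"result": result, "summary": summary, "outdir": outdir}
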