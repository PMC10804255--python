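"""PPV estimation, interval-floor curves and deduplication-rule derivation.

The PPV (positive predictive value) of a stratum of code pairs is the
probability that the second code in a pair marks a suicide-attempt event
distinct from the one indexed by the first code:

    PPV = k / n,   95% CI = PPV ± 1.96 · sqrt(PPV(1−PPV)/n)

with k the number of chart-confirmed distinct pairs of n pairs.  The CI is
the *unclipped* Wald normal approximation — upper bounds may exceed 1 for
small strata — and pairs are treated as independent observations (no
within-patient clustering), mirroring how predictive-modelling pipelines
consume the codes.

An *interval floor* d restricts a stratum to pairs at least d days apart;
PPV is non-decreasing in d in expectation because leaked codes cluster
close to their source event.  :func:`derive_rule` finds, per stratum, the
smallest floor whose PPV meets a benchmark (default 0.90) and packages the
ED and all-pairs floors as a :class:`RuleSpec`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "wald_ci",
    "PPVEstimate",
    "RuleSpec",
    "SETTING_TYPES",
    "RULE_STRATA",
    "stratum_mask",
    "ppv_by_setting",
    "ppv_by_method",
    "method_cross_table",
    "ppv_by_interval_bin",
    "interval_floor_curve",
    "derive_rule",
    "round_half_up",
]

logger = logging.getLogger("sadedup")

SETTING_TYPES = ("nonED_nonED", "ED_nonED", "nonED_ED", "ED_ED")

#: Strata examined when deriving the rule: the four setting types, the two
#: method-concordance types, the pooled second-code-in-ED stratum and all
#: pairs.
RULE_STRATA = SETTING_TYPES + ("same_method", "different_method", "second_ED", "all")

#: Priority order for reducing a multi-method day to one category
#: (specific methods first, ``other`` last).
METHOD_PRIORITY = (
    "poisoning",
    "cutting_piercing",
    "hanging_strangulation_suffocation",
    "jumping",
    "firearm",
    "other",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def wald_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Unclipped Wald normal-approximation CI for a binomial proportion.

    Returns ``(p − z·sqrt(p(1−p)/n), p + z·sqrt(p(1−p)/n))`` with
    ``p = k/n``; bounds are *not* clipped to [0, 1].  ``n = 0`` is an
    undefined estimate and raises rather than returning 0.
    """
    if n < 1:
        raise ValueError("Wald CI undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    half_width = z * math.sqrt(p * (1.0 - p) / n)
    return (p - half_width, p + half_width)


@dataclass(frozen=True)
class PPVEstimate:
    """k distinct of n code pairs, with point estimate and 95% Wald CI."""

    n_pairs: int
    n_distinct: int
    ppv: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: int, n: int, z: float = 1.96) -> "PPVEstimate":
        if n == 0:
            # undefined estimate, signalled as NaN fields (never 0)
            return cls(0, 0, float("nan"), float("nan"), float("nan"))
        low, high = wald_ci(k, n, z)
        return cls(n, k, k / n, low, high)

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(ppv, ci_low, ci_high) rounded half-up, as printed in reports."""
        return tuple(round_half_up(v, ndigits) for v in (self.ppv, self.ci_low, self.ci_high))


@dataclass
class RuleSpec:
    """A derived deduplication rule.

    A later coded day is a new event when it is an ED day at least
    ``ed_floor_days`` after the immediately preceding coded day, or (if
    ``global_floor_days`` is set) any day at least that far after the
    preceding coded day.  ``index_event_policy`` fixes how the very first
    coded day of a record — which has no preceding code to measure from —
    is treated.
    """

    benchmark: float = 0.90
    ed_floor_days: Optional[int] = 5
    global_floor_days: Optional[int] = None
    index_event_policy: str = "first_code_is_event"

    def __post_init__(self) -> None:
        if not 0 < self.benchmark <= 1:
            raise ValueError("benchmark must be in (0, 1]")
        for name in ("ed_floor_days", "global_floor_days"):
            v = getattr(self, name)
            if v is not None:
                v = int(v)
                if v < 1:
                    raise ValueError(f"{name} must be >= 1 when present")
                setattr(self, name, v)
        if self.index_event_policy not in ("first_code_is_event", "first_code_ignored"):
            raise ValueError(f"unknown index_event_policy {self.index_event_policy!r}")

    @classmethod
    def default(cls) -> "RuleSpec":
        """The headline rule: ED code ≥ 5 days after the preceding code."""
        return cls()

    @classmethod
    def permissive(cls) -> "RuleSpec":
        """ED floor 5 days plus the 53-day all-pairs floor for non-ED codes."""
        return cls(ed_floor_days=5, global_floor_days=53)

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str) -> "RuleSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Stratum selection


def stratum_mask(pairs: pd.DataFrame, stratum: str) -> pd.Series:
    """Boolean mask selecting a named stratum of the pair table."""
    if stratum == "all":
        return pd.Series(True, index=pairs.index)
    if stratum in SETTING_TYPES:
        return pairs["setting_type"] == stratum
    if stratum == "same_method":
        return pairs["same_method"].astype(bool)
    if stratum == "different_method":
        return ~pairs["same_method"].astype(bool)
    if stratum == "second_ED":
        return pairs["second_ed"].astype(bool)
    raise ValueError(f"unknown stratum {stratum!r}")


def _require_labels(pairs: pd.DataFrame) -> pd.Series:
    lab = pairs["distinct_label"]
    if lab.isna().any():
        raise ValueError(
            "pairs carry missing distinct labels; label them from a truth "
            "table (synth.label_pairs) or a chart-review label source first"
        )
    return lab.astype(bool)


def _interval_summary(iv: pd.Series) -> dict:
    if len(iv) == 0:
        return {"interval_median": float("nan"), "interval_q1": float("nan"),
                "interval_q3": float("nan"), "interval_mean": float("nan"),
                "interval_sd": float("nan")}
    return {
        "interval_median": float(iv.median()),
        "interval_q1": float(iv.quantile(0.25)),
        "interval_q3": float(iv.quantile(0.75)),
        "interval_mean": float(iv.mean()),
        "interval_sd": float(iv.std(ddof=1)) if len(iv) > 1 else float("nan"),
    }


def _estimate_row(pairs: pd.DataFrame, mask: pd.Series, label: str,
                  total: int) -> dict:
    sub = pairs[mask]
    lab = sub["distinct_label"].astype(bool)
    est = PPVEstimate.from_counts(int(lab.sum()), len(sub))
    row = {
        "stratum": label,
        "n_pairs": len(sub),
        "pct_of_pairs": round_half_up(100.0 * len(sub) / total, 1) if total else float("nan"),
        **_interval_summary(sub["interval_days"]),
        "n_distinct": int(lab.sum()),
        "ppv": est.ppv,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
    }
    return row


def ppv_by_setting(pairs: pd.DataFrame) -> pd.DataFrame:
    """PPV per setting-pair type plus the overall row (report layout:
    pair counts and shares, interval median/quartiles/mean/SD, k, PPV, CI)."""
    _require_labels(pairs)
    total = len(pairs)
    rows = [_estimate_row(pairs, stratum_mask(pairs, s), s, total) for s in SETTING_TYPES]
    rows.append(_estimate_row(pairs, stratum_mask(pairs, "all"), "overall", total))
    return pd.DataFrame(rows)


def ppv_by_method(pairs: pd.DataFrame) -> pd.DataFrame:
    """PPV for same-method vs different-method pairs plus the overall row."""
    _require_labels(pairs)
    total = len(pairs)
    rows = [
        _estimate_row(pairs, stratum_mask(pairs, "same_method"), "same_method", total),
        _estimate_row(pairs, stratum_mask(pairs, "different_method"), "different_method", total),
        _estimate_row(pairs, stratum_mask(pairs, "all"), "overall", total),
    ]
    return pd.DataFrame(rows)


def _primary_method(methods: frozenset) -> str:
    for m in METHOD_PRIORITY:
        if m in methods:
            return m
    return "other"


def method_cross_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """PPV per (first-day, second-day) method-category combination.

    Multi-method days are reduced to their highest-priority specific
    category (``other`` last) — a deterministic tie-break.
    """
    _require_labels(pairs)
    p = pairs.assign(
        first_cat=pairs["first_methods"].map(_primary_method),
        second_cat=pairs["second_methods"].map(_primary_method),
    )
    rows = []
    for (a, b), grp in p.groupby(["first_cat", "second_cat"], sort=True):
        lab = grp["distinct_label"].astype(bool)
        est = PPVEstimate.from_counts(int(lab.sum()), len(grp))
        rows.append({"first_method": a, "second_method": b, "n_pairs": len(grp),
                     "n_distinct": int(lab.sum()), "ppv": est.ppv,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows, columns=["first_method", "second_method", "n_pairs",
                                       "n_distinct", "ppv", "ci_low", "ci_high"])


def interval_bin_label(interval: int, width: int = 7, pool_from: int = 92) -> str:
    if interval >= pool_from:
        return f"{pool_from}+"
    lo = ((interval - 1) // width) * width + 1
    return f"{lo}-{lo + width - 1}"


def ppv_by_interval_bin(pairs: pd.DataFrame, width: int = 7,
                        pool_from: int = 92) -> pd.DataFrame:
    """PPV per 7-day interval bin (1–7, 8–14, …, 85–91, 92+) plus overall."""
    _require_labels(pairs)
    total = len(pairs)
    labels = [f"{lo}-{lo + width - 1}" for lo in range(1, pool_from, width)]
    labels.append(f"{pool_from}+")
    binned = pairs["interval_days"].map(lambda d: interval_bin_label(int(d), width, pool_from))
    rows = []
    for lab in labels:
        rows.append(_estimate_row(pairs, binned == lab, lab, total))
    rows.append(_estimate_row(pairs, stratum_mask(pairs, "all"), "overall", total))
    out = pd.DataFrame(rows)
    return out.drop(columns=["interval_median", "interval_q1", "interval_q3",
                             "interval_mean", "interval_sd"])


def interval_floor_curve(pairs: pd.DataFrame, stratum: str = "all") -> pd.DataFrame:
    """PPV over pairs with interval ≥ d, for every floor d up to the stratum max.

    Columns: ``stratum, floor, n, k, ppv, ci_low, ci_high``.  ``n`` is
    non-increasing in the floor; at floor 1 the estimate equals the
    stratum's overall PPV.
    """
    lab = _require_labels(pairs)
    sub = pairs[stratum_mask(pairs, stratum)]
    if sub.empty:
        return pd.DataFrame(columns=["stratum", "floor", "n", "k", "ppv", "ci_low", "ci_high"])
    iv = np.sort(sub["interval_days"].to_numpy())
    iv_distinct = np.sort(sub.loc[sub["distinct_label"].astype(bool), "interval_days"].to_numpy())
    floors = np.arange(1, iv.max() + 1)
    n_at = len(iv) - np.searchsorted(iv, floors, side="left")
    k_at = len(iv_distinct) - np.searchsorted(iv_distinct, floors, side="left")
    rows = []
    for d, n, k in zip(floors, n_at, k_at):
        est = PPVEstimate.from_counts(int(k), int(n))
        rows.append({"stratum": stratum, "floor": int(d), "n": int(n), "k": int(k),
                     "ppv": est.ppv, "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)


def _floor_from_curve(curve: pd.DataFrame, benchmark: float, strict: bool) -> Optional[int]:
    ok = curve[(curve["n"] > 0) & (curve["ppv"] >= benchmark)]
    if ok.empty:
        return None
    if not strict:
        return int(ok["floor"].iloc[0])
    # strict: every populated floor at or above the chosen one must qualify
    populated = curve[curve["n"] > 0]
    qualifying = set(ok["floor"])
    for d in sorted(qualifying):
        if all(f in qualifying for f in populated.loc[populated["floor"] >= d, "floor"]):
            return int(d)
    return None


def derive_rule(
    pairs: pd.DataFrame,
    benchmark: float = 0.90,
    strict: bool = False,
    include_global_floor: bool = False,
    index_event_policy: str = "first_code_is_event",
) -> tuple[RuleSpec, pd.DataFrame]:
    """Derive the interval-floor deduplication rule from labeled pairs.

    For each stratum in :data:`RULE_STRATA` the smallest floor d with
    PPV(interval ≥ d) ≥ ``benchmark`` is located (absent when never
    reached; ``strict=True`` additionally requires every later populated
    floor to qualify).  The rule's ED floor is taken from the pooled
    second-code-in-ED stratum and the optional global floor from the
    all-pairs stratum.

    Returns the :class:`RuleSpec` and a per-stratum report frame
    (``stratum, n_pairs, floor_days, n_at_floor, ppv_at_floor``).
    """
    _require_labels(pairs)
    floors: dict[str, Optional[int]] = {}
    report_rows = []
    for stratum in RULE_STRATA:
        curve = interval_floor_curve(pairs, stratum)
        if curve.empty:
            logger.warning("stratum %s has no pairs; floor absent", stratum)
            floors[stratum] = None
            report_rows.append({"stratum": stratum, "n_pairs": 0, "floor_days": pd.NA,
                                "n_at_floor": pd.NA, "ppv_at_floor": float("nan")})
            continue
        d = _floor_from_curve(curve, benchmark, strict)
        floors[stratum] = d
        at = curve[curve["floor"] == d].iloc[0] if d is not None else None
        report_rows.append({
            "stratum": stratum,
            "n_pairs": int(curve["n"].iloc[0]),
            "floor_days": d if d is not None else pd.NA,
            "n_at_floor": int(at["n"]) if at is not None else pd.NA,
            "ppv_at_floor": float(at["ppv"]) if at is not None else float("nan"),
        })
    rule = RuleSpec(
        benchmark=benchmark,
        ed_floor_days=floors["second_ED"],
        global_floor_days=floors["all"] if include_global_floor else None,
        index_event_policy=index_event_policy,
    )
    report = pd.DataFrame(report_rows).astype({"floor_days": "Int64", "n_at_floor": "Int64"})
    return rule, report


def plot_floor_curves(
    pairs: pd.DataFrame,
    strata: Sequence[str] = SETTING_TYPES + ("all",),
    benchmark: float = 0.90,
    path: Optional[str] = None,
    max_floor: Optional[int] = 90,
):
    """Plot PPV-vs-interval-floor curves with the benchmark crossing marked.

    Requires matplotlib (the ``plots`` extra); returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for stratum in strata:
        curve = interval_floor_curve(pairs, stratum)
        if curve.empty:
            continue
        if max_floor is not None:
            curve = curve[curve["floor"] <= max_floor]
        color = "0.5" if stratum == "all" else None
        (line,) = ax.plot(curve["floor"], curve["ppv"], label=stratum, color=color)
        hit = curve[curve["ppv"] >= benchmark]
        if not hit.empty:
            d = hit.iloc[0]
            ax.plot([d["floor"]], [d["ppv"]], "o", color=line.get_color())
            ax.annotate(f"{int(d['floor'])} d", (d["floor"], d["ppv"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.axhline(benchmark, linestyle="--", color="k", linewidth=0.8)
    ax.set_xlabel("interval floor (days)")
    ax.set_ylabel("PPV over pairs with interval ≥ floor")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
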