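"""Scikit-learn style estimator wrapping rule derivation and application.

:class:`IntervalFloorRule` is *fit* on a labeled code-pair table (learning
the per-stratum interval floors at the PPV benchmark) and then *predicts*
distinct-vs-leaked status for unlabeled day-aggregated code streams.  It
composes with :func:`sklearn.base.clone`, ``get_params``/``set_params``
and pipeline-style workflows, but scikit-learn itself is not required —
the class degrades to a plain estimator when sklearn is absent.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import stats
from .dedup import apply_rule
from .stats import RuleSpec

try:  # pragma: no cover - import guard
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # minimal get_params/set_params stand-in
        def get_params(self, deep=True):
            import inspect

            names = inspect.signature(type(self).__init__).parameters
            return {k: getattr(self, k) for k in names if k != "self"}

        def set_params(self, **params):
            for k, v in params.items():
                if k not in self.get_params():
                    raise ValueError(f"invalid parameter {k!r}")
                setattr(self, k, v)
            return self

__all__ = ["IntervalFloorRule"]


class IntervalFloorRule(BaseEstimator):
    """Derive and apply an interval-floor deduplication rule.

    Parameters
    ----------
    benchmark : float, default 0.90
        PPV level a stratum's floor must reach.
    strict : bool, default False
        Require every populated floor at or above the chosen one to meet
        the benchmark (instead of the smallest crossing).
    use_global_floor : bool, default False
        Also arm the all-pairs floor, so non-ED days far enough from the
        preceding code count as events.
    index_event_policy : {"first_code_is_event", "first_code_ignored"}
        Treatment of the first coded day of each record.
    interval_reference : {"preceding_code", "since_last_event"}
        Which anchor the interval at prediction time is measured from.

    Attributes
    ----------
    floors_ : dict
        Per-stratum smallest qualifying floor (None when never reached).
    ed_floor_days_ : int or None
        Floor of the pooled second-code-in-ED stratum.
    global_floor_days_ : int or None
        All-pairs floor (None unless ``use_global_floor``).
    rule_spec_ : RuleSpec
        The rule handed to :func:`sadedup.dedup.apply_rule`.
    report_ : DataFrame
        Per-stratum derivation report (n, floor, PPV at floor).
    n_pairs_ : int
        Number of labeled pairs seen at fit time.
    """

    def __init__(
        self,
        benchmark: float = 0.90,
        strict: bool = False,
        use_global_floor: bool = False,
        index_event_policy: str = "first_code_is_event",
        interval_reference: str = "preceding_code",
    ):
        self.benchmark = benchmark
        self.strict = strict
        self.use_global_floor = use_global_floor
        self.index_event_policy = index_event_policy
        self.interval_reference = interval_reference

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "IntervalFloorRule":
        """Derive floors from a labeled pair table.

        ``X`` is a pair table from :func:`sadedup.events.build_pairs`;
        ``y`` optionally supplies the distinctness labels (otherwise the
        ``distinct_label`` column is used).
        """
        pairs = X.copy()
        if y is not None:
            pairs["distinct_label"] = np.asarray(y, dtype=bool)
        rule, report = stats.derive_rule(
            pairs,
            benchmark=self.benchmark,
            strict=self.strict,
            include_global_floor=self.use_global_floor,
            index_event_policy=self.index_event_policy,
        )
        self.rule_spec_ = rule
        self.report_ = report
        self.floors_ = dict(zip(report["stratum"], [None if pd.isna(v) else int(v)
                                                    for v in report["floor_days"]]))
        self.ed_floor_days_ = rule.ed_floor_days
        self.global_floor_days_ = rule.global_floor_days
        self.n_pairs_ = len(pairs)
        return self

    @classmethod
    def from_rule_spec(cls, rule: RuleSpec,
                       interval_reference: str = "preceding_code") -> "IntervalFloorRule":
        """Build an already-'fitted' estimator from a stored rule."""
        est = cls(benchmark=rule.benchmark,
                  use_global_floor=rule.global_floor_days is not None,
                  index_event_policy=rule.index_event_policy,
                  interval_reference=interval_reference)
        est.rule_spec_ = rule
        est.ed_floor_days_ = rule.ed_floor_days
        est.global_floor_days_ = rule.global_floor_days
        est.floors_ = {}
        est.report_ = pd.DataFrame()
        est.n_pairs_ = 0
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "rule_spec_"):
            raise AttributeError("IntervalFloorRule is not fitted; call fit() first")

    # ------------------------------------------------------------------
    def annotate(self, day_events: pd.DataFrame) -> pd.DataFrame:
        """Full per-day labelling (patient, date, reason, event index)."""
        self._check_fitted()
        return apply_rule(day_events, self.rule_spec_,
                          interval_reference=self.interval_reference)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean distinct-event flag per patient-day row of ``X``."""
        return self.annotate(X)["is_distinct_event"].to_numpy(dtype=bool)

    def score(self, X: pd.DataFrame, y) -> float:
        """Per-day precision of distinct calls against boolean truth ``y``."""
        pred = self.predict(X)
        true = np.asarray(y, dtype=bool)
        if pred.sum() == 0:
            return float("nan")
        return float((pred & true).sum() / pred.sum())
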