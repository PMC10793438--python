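"""Benchmarking in-silico variant-effect predictors against functional classes.

Predictor score tables are binarised to damaging/tolerated calls with
direction-aware per-predictor cutoffs (categorical predictors map their
classes directly; "ambiguous" groups with tolerated).  Binary calls are
scored against the assay's functional classes as a 2x2 confusion matrix with
sensitivity, specificity, PPV, NPV and accuracy, and combined into
majority-vote ensembles.  The module also carries the two contingency tests
used in the analysis: an uncorrected Pearson chi-square and a one-sided
Fisher exact test.

The default binarisation cutoffs are widely used published conventions (the
assay itself prescribes none) and every one of them is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CUTOFFS",
    "ConfusionMetrics",
    "binarize_scores",
    "confusion_metrics",
    "ensemble_majority",
    "contingency_chisq",
    "fisher_exact_one_sided",
]

DAMAGING, TOLERATED = "damaging", "tolerated"

#: Per-predictor binarisation rules.  ``kind="score"`` rules compare the (mean)
#: numeric score against ``threshold`` in the direction ``damaging_if``
#: ("ge" or "lt"); ``kind="category"`` rules map the categorical prediction,
#: with anything outside ``damaging`` (including "ambiguous") -> tolerated.
DEFAULT_CUTOFFS: dict[str, dict] = {
    "CADD": {"kind": "score", "threshold": 20.0, "damaging_if": "ge"},
    "PolyPhen-2": {"kind": "category", "damaging": {"probably_damaging", "possibly_damaging"}},
    "SIFT": {"kind": "score", "threshold": 0.05, "damaging_if": "lt"},
    "VEST": {"kind": "score", "threshold": 0.5, "damaging_if": "ge"},
    "AlphaMissense": {"kind": "category", "damaging": {"pathogenic", "likely_pathogenic"}},
    "ESM1b": {"kind": "score", "threshold": -7.5, "damaging_if": "lt"},
    "PrimateAI-3D": {"kind": "score", "threshold": 0.5, "damaging_if": "ge"},
}


def binarize_scores(
    score_table: pd.DataFrame,
    cutoff_config: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Reduce a long predictor table to per-(variant, predictor) binary calls.

    ``score_table`` columns: ``variant``, ``predictor``, and ``score`` and/or
    ``category``.  Multiple numeric scores for one variant are reduced by
    their mean before the cutoff.  Rows with neither score nor category are
    treated as missing and excluded (they simply produce no call).  Raises
    ``KeyError`` for a predictor with no configured cutoff.
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoff_config is None else cutoff_config)
    calls = []
    for (variant, predictor), group in score_table.groupby(["variant", "predictor"], sort=True):
        try:
            rule = cutoffs[predictor]
        except KeyError:
            raise KeyError(f"no cutoff configured for predictor {predictor!r}") from None
        if rule["kind"] == "score":
            scores = pd.to_numeric(group.get("score"), errors="coerce").dropna()
            if scores.empty:
                continue  # missing for this predictor
            mean = float(scores.mean())
            if rule["damaging_if"] == "ge":
                call = DAMAGING if mean >= rule["threshold"] else TOLERATED
            elif rule["damaging_if"] == "lt":
                call = DAMAGING if mean < rule["threshold"] else TOLERATED
            else:
                raise ValueError(f"unknown direction {rule['damaging_if']!r}")
        elif rule["kind"] == "category":
            cats = group.get("category")
            cats = cats.dropna() if cats is not None else pd.Series(dtype=object)
            if cats.empty:
                continue
            call = DAMAGING if str(cats.iloc[0]) in rule["damaging"] else TOLERATED
        else:
            raise ValueError(f"unknown cutoff kind {rule['kind']!r}")
        calls.append((variant, predictor, call))
    return pd.DataFrame(calls, columns=["variant", "predictor", "call"])


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion counts plus the five derived proportions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
        }


def confusion_metrics(
    truth_classes: Mapping[str, str] | pd.Series,
    calls: Mapping[str, str] | pd.Series,
    indeterminate_policy: str = "exclude",
) -> ConfusionMetrics:
    """Score damaging/tolerated calls against functional classes.

    Positives are functionally deleterious truth variants.  Variants of
    indeterminate function are excluded by default, or folded into a truth
    side with ``indeterminate_policy`` in {"exclude", "as_damaging_truth",
    "as_tolerated_truth"}.  Variants without a call are excluded (missing).
    """
    if indeterminate_policy not in ("exclude", "as_damaging_truth", "as_tolerated_truth"):
        raise ValueError(f"unknown indeterminate policy {indeterminate_policy!r}")
    truth = pd.Series(dict(truth_classes)) if not isinstance(truth_classes, pd.Series) else truth_classes
    pred = pd.Series(dict(calls)) if not isinstance(calls, pd.Series) else calls
    tp = fp = tn = fn = 0
    for variant in truth.index.intersection(pred.index):
        cls, call = truth[variant], pred[variant]
        if cls == "indeterminate":
            if indeterminate_policy == "exclude":
                continue
            cls = "deleterious" if indeterminate_policy == "as_damaging_truth" else "neutral"
        positive_truth = cls == "deleterious"
        positive_call = call == DAMAGING
        if positive_truth and positive_call:
            tp += 1
        elif positive_truth:
            fn += 1
        elif positive_call:
            fp += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise ValueError("no evaluable variants (empty truth/call overlap)")
    return ConfusionMetrics(tp, fp, tn, fn)


def ensemble_majority(
    calls_by_predictor: pd.DataFrame,
    quorum: int | None = None,
) -> pd.Series:
    """Majority-vote ensemble call per variant.

    ``calls_by_predictor`` is a variant x predictor frame of
    damaging/tolerated calls with NaN for missing.  A variant is damaging
    when its damaging votes reach the quorum among predictors with available
    calls; the default quorum is ``ceil((k + 1) / 2)`` for ``k`` available
    predictors (4 of 7, 3 of 5).  Variants with no available calls are
    returned as NaN (missing).
    """
    if quorum is not None and quorum < 1:
        raise ValueError("quorum must be >= 1")
    out = {}
    for variant, row in calls_by_predictor.iterrows():
        avail = row.dropna()
        if avail.empty:
            out[variant] = np.nan
            continue
        k = len(avail)
        need = quorum if quorum is not None else math.ceil((k + 1) / 2)
        votes = int((avail == DAMAGING).sum())
        out[variant] = DAMAGING if votes >= need else TOLERATED
    return pd.Series(out, name="ensemble")


def _check_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.floor(arr)):
        raise ValueError("table cells must be non-negative integers")
    return arr.astype(np.int64)


def contingency_chisq(table_2x2) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    arr = _check_table(table_2x2)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact_one_sided(table_2x2) -> float:
    """One-sided Fisher exact p-value for depletion in the first row.

    The tail is the hypergeometric probability, conditional on the margins,
    that the [0, 0] cell is at most its observed value; computed through the
    log-space hypergeometric CDF for stability.  Degenerate tables (a zero
    row or column margin) carry no information and return 1.
    """
    arr = _check_table(table_2x2)
    a = int(arr[0, 0])
    row1 = int(arr[0].sum())
    col1 = int(arr[:, 0].sum())
    total = int(arr.sum())
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        return 1.0
    logp = stats.hypergeom.logcdf(a, total, col1, row1)
    return float(min(1.0, math.exp(logp)))
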