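"""Validation of copy-number calls against reference truth sets.

Given a truth set of genes with reliably known copy-number status
(expanded / single copy / reduced), predictions are scored with the
standard confusion-matrix triple, all expressed as percentages:

* sensitivity = TP / (TP + FN) — true positives correctly identified,
* specificity = TN / (TN + FP) — true negatives correctly identified,
* precision   = TP / (TP + FP) — true positives among predicted positives.

Truth genes absent from the call table are treated as predicted
negative (with a logged warning), the conservative reading.

For simulation benchmarks with planted copy states,
:func:`recovery_metrics` additionally separates *detection* sensitivity
(direction-concordant significance: adjusted p <= alpha with the fold
change in the planted direction) from strict threshold-*classification*
sensitivity.  When the planted effect sits exactly on the fold-change
threshold (a 2x duplication against an up-threshold of +1), the
estimated fold change is symmetric around the cut-off and threshold
classification of such genes is a coin flip by construction; detection
sensitivity is the meaningful power measure there, while false-positive
rate and precision keep the strict classification rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    CNE,
    CNR,
    EXPANDED,
    NEUTRAL,
    REDUCED,
    SINGLE_COPY,
    ValidationError,
    validate_truth,
)

logger = logging.getLogger(__name__)

#: call class corresponding to each positive truth status
_POSITIVE_TRUTH = {CNE: EXPANDED, CNR: REDUCED}


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float  # NaN when no predicted positives

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(
    calls: pd.DataFrame,
    truth: pd.Series,
    positive_class: str = CNE,
) -> ConfusionMetrics:
    """Score calls against a truth set for one positive class.

    ``calls`` uses probeset/gene ids in the column matching the truth
    index (gene_id preferred, falling back to probeset_id).
    """
    if positive_class not in _POSITIVE_TRUTH:
        raise ValidationError(f"positive_class must be CNE or CNR, got {positive_class!r}")
    truth = validate_truth(truth)
    if truth.empty:
        raise ValidationError("empty truth set")

    id_col = "gene_id" if "gene_id" in calls.columns and calls["gene_id"].astype(str).str.len().gt(0).any() else "probeset_id"
    call_cls = calls.set_index(id_col)["cnd_class"]
    call_cls = call_cls[~call_cls.index.duplicated()]
    missing = truth.index.difference(call_cls.index)
    if len(missing):
        logger.warning(
            "%d truth genes absent from calls; counted as predicted negative",
            len(missing),
        )
    predicted = call_cls.reindex(truth.index).fillna(NEUTRAL)

    pos_truth = truth == _POSITIVE_TRUTH[positive_class]
    pos_pred = predicted == positive_class
    tp = int((pos_truth & pos_pred).sum())
    fp = int((~pos_truth & pos_pred).sum())
    fn = int((pos_truth & ~pos_pred).sum())
    tn = int((~pos_truth & ~pos_pred).sum())

    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    prec = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, prec)


def method_comparison(
    methods: Mapping[str, Callable[[], pd.DataFrame]],
    truth: pd.Series,
    positive_class: str = CNE,
) -> pd.DataFrame:
    """Head-to-head comparison of calling pipelines on one dataset.

    ``methods`` maps a method name to a zero-argument callable returning
    a calls table.  A failing method yields a flagged row; the others
    are unaffected.
    """
    rows = []
    for name, run in methods.items():
        try:
            calls = run()
            cm = confusion_metrics(calls, truth, positive_class)
            n_calls = int((calls["cnd_class"] == positive_class).sum())
            rows.append(
                {
                    "method": name,
                    "total_calls": n_calls,
                    "sensitivity": cm.sensitivity,
                    "specificity": cm.specificity,
                    "precision": cm.precision,
                    "failed": False,
                }
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-method failures
            logger.warning("method %s failed: %s", name, exc)
            rows.append(
                {
                    "method": name,
                    "total_calls": 0,
                    "sensitivity": float("nan"),
                    "specificity": float("nan"),
                    "precision": float("nan"),
                    "failed": True,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Planted-truth benchmark summary (percent scales)."""

    sensitivity_detection: float
    sensitivity_class: float
    fpr_class: float
    precision_class: float
    n_planted: int
    n_neutral: int


def recovery_metrics(
    calls: pd.DataFrame,
    truth: pd.Series,
    positive_class: str = CNE,
    alpha: float = 0.1,
) -> RecoveryMetrics:
    """Score recovery of planted copy-number states in a simulation.

    Detection sensitivity: fraction of planted positives with adjusted
    p <= alpha and fold change in the planted direction.  Classification
    sensitivity / FPR / precision use the strict call classes.
    """
    truth = validate_truth(truth)
    id_col = "gene_id" if "gene_id" in calls.columns and calls["gene_id"].astype(str).str.len().gt(0).any() else "probeset_id"
    tbl = calls.set_index(id_col)
    tbl = tbl[~tbl.index.duplicated()]
    aligned = tbl.reindex(truth.index)

    pos_status = _POSITIVE_TRUTH[positive_class]
    planted = truth == pos_status
    neutral_truth = truth == SINGLE_COPY
    sign = 1.0 if positive_class == CNE else -1.0

    detected = (aligned["p_adj"] <= alpha) & (sign * aligned["log2_fc"] > 0)
    classed = aligned["cnd_class"] == positive_class
    any_call = aligned["cnd_class"].isin([CNE, CNR])

    n_planted = int(planted.sum())
    n_neutral = int(neutral_truth.sum())
    sens_det = 100.0 * float(detected[planted].fillna(False).mean()) if n_planted else float("nan")
    sens_cls = 100.0 * float(classed[planted].fillna(False).mean()) if n_planted else float("nan")
    fpr = 100.0 * float(any_call[neutral_truth].fillna(False).mean()) if n_neutral else float("nan")
    n_pos_calls = int(classed.fillna(False).sum())
    prec = (
        100.0 * float((classed & planted).fillna(False).sum()) / n_pos_calls
        if n_pos_calls
        else float("nan")
    )
    return RecoveryMetrics(sens_det, sens_cls, fpr, prec, n_planted, n_neutral)
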