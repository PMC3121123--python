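"""Confusion-matrix bookkeeping and the six residue-level performance measures.

The measures follow the conventions of the DNA-binding-residue prediction
literature: accuracy, sensitivity, specificity, strength (the arithmetic mean
of sensitivity and specificity, a balance measure for heavily imbalanced
residue datasets), Matthews correlation coefficient and F-measure.

Counts are kept as non-negative reals rather than integers so that confusion
matrices can be *reconstructed* from published rates and class totals
(``reconstruct_counts``), which is how the published benchmark comparison of
six sequence-based predictors and the stacked meta-predictor is validated
here (``benchmark_consistency``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "confusion_from_arrays",
    "metrics",
    "reconstruct_counts",
    "round_half_up",
    "BENCHMARK_POSITIVES",
    "BENCHMARK_NEGATIVES",
    "PUBLISHED_BENCHMARK",
    "benchmark_consistency",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "strength", "mcc", "f_measure")

#: Residue class totals of the published structure-derived benchmark
#: (positives = DNA-binding residues at the 3.5 Angstrom any-atom cutoff).
BENCHMARK_POSITIVES = 5342
BENCHMARK_NEGATIVES = 67396

#: Published residue-level results (10-fold CV for the meta-predictor, single
#: runs for the six base predictors) on the same benchmark, as printed:
#: method -> (accuracy, sensitivity, specificity, strength, mcc, f_measure).
PUBLISHED_BENCHMARK: Mapping[str, tuple[float, ...]] = {
    "meta": (0.77, 0.77, 0.77, 0.77, 0.32, 0.33),
    "bindn": (0.78, 0.54, 0.80, 0.67, 0.21, 0.26),
    "bindn_rf": (0.82, 0.67, 0.83, 0.75, 0.32, 0.34),
    "dbs_pred": (0.75, 0.53, 0.76, 0.65, 0.17, 0.23),
    "disis": (0.92, 0.19, 0.98, 0.59, 0.25, 0.27),
    "dnabindr": (0.73, 0.66, 0.74, 0.70, 0.23, 0.26),
    "dpbind": (0.78, 0.69, 0.79, 0.74, 0.29, 0.31),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cells; reals to support rate-based reconstruction."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> float:
        return self.tp + self.fn

    @property
    def negatives(self) -> float:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """The six measures; metrics with a vanishing denominator are NaN and
    listed in ``undefined`` instead of being coerced to 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    strength: float
    mcc: float
    f_measure: float
    undefined: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_from_arrays(predicted, truth) -> ConfusionCounts:
    """Tally the four cells from two equal-length binary (1/0) arrays."""
    p = np.asarray(predicted).astype(int)
    t = np.asarray(truth).astype(int)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs truth {t.shape}")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValueError("labels must be binary 1/0")
    return ConfusionCounts(
        tp=float(np.sum((p == 1) & (t == 1))),
        tn=float(np.sum((p == 0) & (t == 0))),
        fp=float(np.sum((p == 1) & (t == 0))),
        fn=float(np.sum((p == 0) & (t == 1))),
    )


def confusion(predicted, truth) -> ConfusionCounts:
    """Confusion counts for two per-residue label tracks.

    Accepts :class:`bindstack.annotate.ResidueLabelTrack` pairs (residue
    identities must agree position-wise) or plain binary arrays.
    """
    from .annotate import ResidueLabelTrack  # local import to avoid a cycle

    if isinstance(predicted, ResidueLabelTrack) and isinstance(truth, ResidueLabelTrack):
        if predicted.residue_ids != truth.residue_ids:
            raise ValueError("residue identities of the two tracks do not match")
        return confusion_from_arrays(predicted.labels, truth.labels)
    return confusion_from_arrays(predicted, truth)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def metrics(counts: ConfusionCounts) -> MetricSet:
    """The six measures from a confusion matrix.

    accuracy=(TP+TN)/total, sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    strength=(sens+spec)/2, MCC=(TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    F=2*precision*sensitivity/(precision+sensitivity).
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts: no metrics defined")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    acc = (tp + tn) / counts.total
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    strength = (sens + spec) / 2  # NaN propagates if either rate is undefined
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    prec = _safe_div(tp, tp + fp)
    f = _safe_div(2 * prec * sens, prec + sens)

    out = MetricSet(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        strength=strength,
        mcc=mcc,
        f_measure=f,
        undefined=frozenset(
            name
            for name, v in zip(
                METRIC_NAMES, (acc, sens, spec, strength, mcc, f)
            )
            if math.isnan(v)
        ),
    )
    return out


def reconstruct_counts(
    sensitivity: float, specificity: float, positives: float, negatives: float
) -> ConfusionCounts:
    """Invert sensitivity/specificity plus class totals into real-valued counts.

    TP = sensitivity*P, FN = P-TP, TN = specificity*N, FP = N-TN.  This lets a
    published results table be validated by recomputing its derived columns.
    """
    for name, rate in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    if positives <= 0 or negatives <= 0:
        raise ValueError("class counts must be positive")
    tp = sensitivity * positives
    tn = specificity * negatives
    return ConfusionCounts(tp=tp, tn=tn, fp=negatives - tn, fn=positives - tp)


def benchmark_consistency(
    rows: Mapping[str, tuple[float, ...]] | None = None,
    positives: int = BENCHMARK_POSITIVES,
    negatives: int = BENCHMARK_NEGATIVES,
) -> pd.DataFrame:
    """Recompute accuracy/strength/MCC/F for each published benchmark row from
    its printed sensitivity/specificity and the class totals.

    Returns a frame with printed and reconstructed cells (rounded half-up to
    2 decimals) and per-cell agreement flags.  Strength and MCC agree for all
    seven methods; accuracy for six of seven (the dbs_pred accuracy cell is
    internally inconsistent with its own printed rates); F-measure is known to
    drift by +/-0.01 on most rows, consistent with it having been computed
    from unrounded internal rates.
    """
    rows = PUBLISHED_BENCHMARK if rows is None else rows
    records = []
    for method, (acc_p, sens_p, spec_p, str_p, mcc_p, f_p) in rows.items():
        m = metrics(reconstruct_counts(sens_p, spec_p, positives, negatives))
        rec = {
            "method": method,
            "accuracy_printed": acc_p,
            "strength_printed": str_p,
            "mcc_printed": mcc_p,
            "f_measure_printed": f_p,
            "accuracy_reconstructed": round_half_up(m.accuracy),
            "strength_reconstructed": round_half_up(m.strength),
            "mcc_reconstructed": round_half_up(m.mcc),
            "f_measure_reconstructed": round_half_up(m.f_measure),
        }
        for name in ("accuracy", "strength", "mcc", "f_measure"):
            rec[f"{name}_match"] = rec[f"{name}_reconstructed"] == rec[f"{name}_printed"]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def best_threshold_strength(scores, truth) -> float:
    """Maximum achievable strength of a single score track over all decision
    thresholds (an oracle-threshold summary of one predictor's discrimination)."""
    from sklearn.metrics import roc_curve

    t = np.asarray(truth).astype(int)
    if np.unique(t).size < 2:
        raise ValueError("both classes required to sweep thresholds")
    fpr, tpr, _ = roc_curve(t, np.asarray(scores, dtype=float))
    return float(np.max((tpr + (1.0 - fpr)) / 2.0))


def metrics_report(
    named_counts: Iterable[tuple[str, ConfusionCounts]]
) -> pd.DataFrame:
    """Tabulate methods x the six measures in the conventional column order."""
    records = []
    for name, counts in named_counts:
        m = metrics(counts)
        records.append({"method": name, **m.as_dict()})
    return pd.DataFrame.from_records(
        records, columns=["method", *METRIC_NAMES]
    )
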