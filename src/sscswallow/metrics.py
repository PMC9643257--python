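"""Diagnostic-accuracy metrics for the binary swallow classifier.

The positive class is *aspirating* (label 1), matching the clinical framing:
sensitivity is the fraction of aspirating swallows caught, specificity the
fraction of normal swallows cleared. Normal-class metrics are obtained by
swapping class roles, so sensitivity(normal) = specificity(aspirating) and
vice versa.

A metric whose denominator is zero (e.g. PPV with no positive predictions)
is reported as undefined (NaN), never silently as 0 — on a single-class
test set a fabricated 0 or 1 would misstate the evidence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from sscswallow.audio_io import ValidationError

METRIC_NAMES = ("ppv", "npv", "specificity", "sensitivity", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 test-set counts; positive class = aspirating (label 1).

    tn: normal predicted normal; fp: normal predicted aspirating;
    fn: aspirating predicted normal; tp: aspirating predicted aspirating.
    """

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def swapped(self) -> "ConfusionMatrix":
        """The same outcomes with normal treated as the positive class."""
        return ConfusionMatrix(tn=self.tp, fp=self.fn, fn=self.fp, tp=self.tn)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=pd.Index(["true_normal", "true_aspirating"]),
            columns=["pred_normal", "pred_aspirating"])


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class diagnostic metrics plus total accuracy.

    ``per_class[c]`` maps metric name -> value in [0, 1] or NaN when the
    defining denominator is zero.
    """

    per_class: dict[int, dict[str, float]]
    accuracy: float


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Cross-tabulate 0/1 labels into a confusion matrix."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValidationError(
            f"label arrays must be 1-D and equal length (got {t.shape} vs {p.shape})")
    for arr, name in ((t, "true"), (p, "predicted")):
        if len(arr) and not np.isin(arr, [0, 1]).all():
            raise ValidationError(f"{name} labels must all be 0 or 1")
    return ConfusionMatrix(tn=int(((t == 0) & (p == 0)).sum()),
                           fp=int(((t == 0) & (p == 1)).sum()),
                           fn=int(((t == 1) & (p == 0)).sum()),
                           tp=int(((t == 1) & (p == 1)).sum()))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _one_class(cm: ConfusionMatrix) -> dict[str, float]:
    sens = _safe_div(cm.tp, cm.tp + cm.fn)
    spec = _safe_div(cm.tn, cm.tn + cm.fp)
    ppv = _safe_div(cm.tp, cm.tp + cm.fp)
    npv = _safe_div(cm.tn, cm.tn + cm.fn)
    f1 = (2 * ppv * sens / (ppv + sens)
          if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
          else float("nan"))
    return {"ppv": ppv, "npv": npv, "specificity": spec,
            "sensitivity": sens, "f1": f1}


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    """PPV, NPV, specificity, sensitivity and F1 for both classes, plus accuracy.

    F1 is the harmonic mean of PPV (precision) and sensitivity (recall) of
    the same class. Accuracy does not depend on which class is positive.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix (no test items)")
    return ClassMetrics(per_class={0: _one_class(cm.swapped()), 1: _one_class(cm)},
                        accuracy=(cm.tp + cm.tn) / cm.total)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.885 -> 0.89 at 2 decimals), NaN-safe."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_table(cm: ConfusionMatrix, decimals: int | None = 2) -> pd.DataFrame:
    """Both classes' metrics as a tidy table, half-up rounded for reporting."""
    m = metrics_from_confusion(cm)
    rows = {}
    for c, name in ((0, "Normal swallow (0)"), (1, "Aspirating swallow (1)")):
        vals = m.per_class[c]
        rows[name] = {k: (round_half_up(vals[k], decimals) if decimals is not None
                          else vals[k]) for k in METRIC_NAMES}
    df = pd.DataFrame(rows).T
    df.columns = ["PPV", "NPV", "Specificity", "Sensitivity", "F1"]
    return df


def evaluation_report(cm: ConfusionMatrix, decimals: int = 2) -> str:
    """Human-readable report: total accuracy header plus the per-class table."""
    m = metrics_from_confusion(cm)
    df = metrics_table(cm, decimals)
    buf = io.StringIO()
    buf.write(f"Total accuracy = {round_half_up(m.accuracy, decimals):.{decimals}f}\n")
    buf.write(df.to_string(float_format=lambda v: f"{v:.{decimals}f}",
                           na_rep="undefined"))
    buf.write("\n")
    return buf.getvalue()


def metrics_csv(cm: ConfusionMatrix, decimals: int | None = None) -> pd.DataFrame:
    """Long-format (class, metric, value) table, full precision by default."""
    m = metrics_from_confusion(cm)
    records = [{"class": cls, "metric": k,
                "value": (round_half_up(v, decimals) if decimals is not None else v)}
               for cls, vals in m.per_class.items() for k, v in vals.items()]
    records.append({"class": "all", "metric": "accuracy",
                    "value": (round_half_up(m.accuracy, decimals)
                              if decimals is not None else m.accuracy)})
    return pd.DataFrame.from_records(records)
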