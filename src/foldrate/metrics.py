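"""Performance assessment for the three-class and regression tasks.

Classification metrics follow the published naming: SPEC is
TP/(TP+FP) (i.e. precision) and SENS is TP/(TP+FN) (recall); both
aliases are carried in the report.  Multi-class accuracy is the sum of
diagonal confusion counts over N, and GC2 is the generalized squared
correlation, a chi-square statistic normalised to [0, 1].

Metrics with a zero denominator are reported as ``None`` and flagged,
never silently coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from foldrate.variant_data import CLASS_ORDER, Label


class MetricError(ValueError):
    """Raised for inconsistent confusion counts or invalid inputs."""


@dataclass
class ConfusionSummary:
    """Per-class confusion counts, optionally with the full K x K matrix.

    Rows of ``z`` are actual classes, columns are predicted classes, so
    ``z[i, j]`` counts items of class i predicted as class j.
    """

    classes: tuple
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n: int
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp, dtype=float)
        self.fp = np.asarray(self.fp, dtype=float)
        self.fn = np.asarray(self.fn, dtype=float)
        k = len(self.classes)
        if not (len(self.tp) == len(self.fp) == len(self.fn) == k):
            raise MetricError("per-class count arrays must match classes")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != (k, k):
                raise MetricError(f"confusion matrix must be {k}x{k}")

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def tn(self) -> np.ndarray:
        return self.n - self.tp - self.fp - self.fn

    @property
    def x(self) -> np.ndarray:
        """Actual class sizes (row sums)."""
        return self.tp + self.fn

    @property
    def y(self) -> np.ndarray:
        """Predicted class sizes (column sums)."""
        return self.tp + self.fp

    @classmethod
    def from_labels(
        cls, truth: Sequence, predicted: Sequence, classes: Sequence | None = None
    ) -> "ConfusionSummary":
        truth = list(truth)
        predicted = list(predicted)
        if len(truth) != len(predicted):
            raise MetricError(
                f"length mismatch: {len(truth)} truths vs "
                f"{len(predicted)} predictions"
            )
        if classes is None:
            classes = (
                CLASS_ORDER
                if all(isinstance(t, Label) for t in truth)
                else tuple(sorted(set(truth) | set(predicted)))
            )
        index = {c: i for i, c in enumerate(classes)}
        k = len(classes)
        z = np.zeros((k, k))
        for t, p in zip(truth, predicted):
            z[index[t], index[p]] += 1
        return cls.from_matrix(z, classes)

    @classmethod
    def from_matrix(cls, z: np.ndarray, classes: Sequence) -> "ConfusionSummary":
        z = np.asarray(z, dtype=float)
        tp = np.diag(z)
        return cls(
            classes=tuple(classes),
            tp=tp,
            fp=z.sum(axis=0) - tp,
            fn=z.sum(axis=1) - tp,
            n=int(round(z.sum())),
            z=z,
        )


def confusion_from_perclass(
    tp: Sequence[float],
    fp: Sequence[float],
    fn: Sequence[float],
    n: int,
    classes: Sequence | None = None,
) -> ConfusionSummary:
    """Build a partial summary from per-class TP/FP/FN counts.

    The marginals ``x`` and ``y`` are recovered exactly, but for K > 2
    the off-diagonal cells are under-determined, so the full matrix is
    left unset and GC2 is unavailable.
    """
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    classes = tuple(classes) if classes is not None else CLASS_ORDER[: len(tp)]
    if tp.sum() > n:
        raise MetricError(
            f"sum of TP counts ({tp.sum():g}) exceeds total N ({n})"
        )
    if not math.isclose((tp + fn).sum(), n, abs_tol=1e-9):
        raise MetricError(
            "actual class sizes (TP+FN) must sum to N: "
            f"{(tp + fn).sum():g} != {n}"
        )
    if not math.isclose((tp + fp).sum(), n, abs_tol=1e-9):
        raise MetricError(
            "predicted class sizes (TP+FP) must sum to N: "
            f"{(tp + fp).sum():g} != {n}"
        )
    return ConfusionSummary(classes=classes, tp=tp, fp=fp, fn=fn, n=n)


@dataclass
class MetricReport:
    """Flat container for one evaluation's metric values.

    ``per_class`` maps class -> {SPEC, SENS, F1} (values may be None
    when undefined); overall fields are None when not applicable to the
    task or undefined, with an explanation in ``flags``.
    """

    task: str
    per_class: dict = field(default_factory=dict)
    macro_f1: float | None = None
    acc: float | None = None
    gc2: float | None = None
    pcc: float | None = None
    mae: float | None = None
    mse: float | None = None
    r2: float | None = None
    n: int = 0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"task": self.task, "n": self.n, "flags": list(self.flags)}
        if self.task == "classify":
            out["per_class"] = {
                str(c): dict(v) for c, v in self.per_class.items()
            }
            out.update(macro_f1=self.macro_f1, acc=self.acc, gc2=self.gc2)
        else:
            out.update(pcc=self.pcc, mae=self.mae, mse=self.mse, r2=self.r2)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.task == "classify":
            for cls, vals in self.per_class.items():
                for name, value in vals.items():
                    rows.append(
                        {"metric": name, "class": str(cls), "value": value}
                    )
            rows += [
                {"metric": "Macro-F1", "class": "all", "value": self.macro_f1},
                {"metric": "ACC", "class": "all", "value": self.acc},
                {"metric": "GC2", "class": "all", "value": self.gc2},
            ]
        else:
            for name, value in (
                ("PCC", self.pcc), ("MAE", self.mae),
                ("MSE", self.mse), ("R2", self.r2),
            ):
                rows.append({"metric": name, "class": "all", "value": value})
        return pd.DataFrame(rows)

    def write(self, path: str | Path, fmt: str = "tsv") -> None:
        path = Path(path)
        if fmt == "json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            self.to_frame().to_csv(path, sep="\t", index=False)


def _safe_div(num: float, den: float):
    return num / den if den > 0 else None


def gc2(z: np.ndarray) -> float:
    """Generalized squared correlation of a K x K confusion matrix.

    chi-square over expected cell counts ``e_ij = x_i * y_j / N``,
    normalised by ``N * (K - 1)``.  Cells whose expected count is zero
    (an empty row or column marginal) contribute nothing.
    """
    z = np.asarray(z, dtype=float)
    n = z.sum()
    if n <= 0:
        raise MetricError("empty confusion matrix")
    k = z.shape[0]
    if k < 2:
        raise MetricError("GC2 needs at least two classes")
    x = z.sum(axis=1)
    y = z.sum(axis=0)
    e = np.outer(x, y) / n
    mask = e > 0
    chi2 = (((z - e) ** 2)[mask] / e[mask]).sum()
    return float(chi2 / (n * (k - 1)))


def classification_metrics(confusion: ConfusionSummary) -> MetricReport:
    """Per-class SPEC/SENS/F1 plus macro-F1, ACC and GC2.

    Works from per-class counts alone; GC2 additionally needs the full
    confusion matrix and is flagged unavailable otherwise.
    """
    if confusion.n <= 0:
        raise MetricError("empty confusion summary")
    report = MetricReport(task="classify", n=confusion.n)
    f1s = []
    for i, cls in enumerate(confusion.classes):
        spec = _safe_div(confusion.tp[i], confusion.tp[i] + confusion.fp[i])
        sens = _safe_div(confusion.tp[i], confusion.tp[i] + confusion.fn[i])
        if spec is None or sens is None or spec + sens == 0:
            f1 = None
            report.flags.append(f"F1 undefined for class {cls}")
        else:
            f1 = 2 * spec * sens / (spec + sens)
        if spec is None:
            report.flags.append(f"SPEC undefined for class {cls} (no predictions)")
        if sens is None:
            report.flags.append(f"SENS undefined for class {cls} (no actuals)")
        report.per_class[cls] = {
            "SPEC": spec,
            "SENS": sens,
            "F1": f1,
            "precision": spec,
            "recall": sens,
        }
        f1s.append(f1)
    if all(f1 is not None for f1 in f1s):
        report.macro_f1 = float(np.mean(f1s))
    else:
        report.flags.append("Macro-F1 undefined (missing per-class F1)")
    report.acc = float(confusion.tp.sum() / confusion.n)
    if confusion.z is not None:
        report.gc2 = gc2(confusion.z)
    else:
        report.flags.append("GC2 unavailable without the full confusion matrix")
    return report


def regression_metrics(
    predictions: Sequence[float], truths: Sequence[float]
) -> MetricReport:
    """PCC, MAE, MSE and R2 of predictions against true values."""
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    if pred.shape != true.shape:
        raise MetricError(
            f"length mismatch: {pred.shape} predictions vs {true.shape} truths"
        )
    if pred.size < 2:
        raise MetricError("need at least two points")
    report = MetricReport(task="regress", n=int(pred.size))
    resid = pred - true
    report.mae = float(np.abs(resid).mean())
    report.mse = float((resid**2).mean())
    ss_tot = float(((true - true.mean()) ** 2).sum())
    if ss_tot > 0:
        report.r2 = 1.0 - float((resid**2).sum()) / ss_tot
    else:
        report.flags.append("R2 undefined: truths have zero variance")
    if true.std() > 0 and pred.std() > 0:
        report.pcc = float(
            np.cov(pred, true, bias=True)[0, 1] / (pred.std() * true.std())
        )
    else:
        report.flags.append("PCC undefined: zero variance input")
    return report
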