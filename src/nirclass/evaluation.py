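"""Confusion counts, one-vs-rest sensitivity/specificity and total accuracy,
plus the per-preprocessing-variant evaluation table.

Sensitivity = TP / (TP + FN) and specificity = TN / (TN + FP), computed
one-vs-rest per class.  Metrics with an empty denominator are reported as
NaN (an explicit undefined marker), never silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SpectraSet
from .preprocessing import PreprocessSpec, apply_preprocess
from .plsda import PLSDAModel, predict_class, train_plsda


@dataclass
class ConfusionCounts:
    classes: list
    matrix: np.ndarray       # B x B, rows = true class, columns = predicted

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def _idx(self, cls) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise KeyError(f"unknown class {cls!r}") from None

    def tp(self, cls) -> int:
        i = self._idx(cls)
        return int(self.matrix[i, i])

    def fn(self, cls) -> int:
        i = self._idx(cls)
        return int(self.matrix[i].sum() - self.matrix[i, i])

    def fp(self, cls) -> int:
        i = self._idx(cls)
        return int(self.matrix[:, i].sum() - self.matrix[i, i])

    def tn(self, cls) -> int:
        return self.total - self.tp(cls) - self.fn(cls) - self.fp(cls)


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     classes: Sequence) -> ConfusionCounts:
    classes = list(classes)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label {t if t not in index else p!r} "
                             f"not among classes {classes!r}")
        M[index[t], index[p]] += 1
    return ConfusionCounts(classes, M)


def sensitivity(counts: ConfusionCounts, cls) -> float:
    """TP / (TP + FN); NaN when the class never occurs in the truth."""
    tp, fn = counts.tp(cls), counts.fn(cls)
    if tp + fn == 0:
        return float("nan")
    return tp / (tp + fn)


def specificity(counts: ConfusionCounts, cls) -> float:
    """TN / (TN + FP); NaN when every sample truly belongs to ``cls``."""
    tn, fp = counts.tn(cls), counts.fp(cls)
    if tn + fp == 0:
        return float("nan")
    return tn / (tn + fp)


def total_accuracy(counts: ConfusionCounts) -> float:
    """Percentage of correctly classified samples, 0-100."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(counts.matrix)) / counts.total


def format_accuracy(pct: float) -> str:
    """One decimal place, half-up (31/36 -> '86.1')."""
    return str(Decimal(repr(pct)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


@dataclass
class VariantResult:
    spec: PreprocessSpec
    model: PLSDAModel
    counts: ConfusionCounts
    n_wrong: int
    accuracy: float          # percent
    sens: dict               # class -> sensitivity
    spec_: dict              # class -> specificity


@dataclass
class EvaluationReport:
    rows: list               # of VariantResult

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"preprocessing": r.spec.method,
                   "selected_k": r.model.k,
                   "wrongly_classified": r.n_wrong,
                   "total_accuracy_pct": format_accuracy(r.accuracy)}
            for c in r.counts.classes:
                rec[f"sens_{c}"] = round(r.sens[c], 4)
                rec[f"spec_{c}"] = round(r.spec_[c], 4)
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def best(self) -> VariantResult:
        return max(self.rows, key=lambda r: r.accuracy)


def evaluate_variants(train: SpectraSet, test: SpectraSet,
                      variants: Sequence[PreprocessSpec],
                      k_max: int = 15, leave_out_fraction: float = 0.3,
                      n_splits: int = 100, f_alpha: float = 0.25,
                      seed: int = 0) -> EvaluationReport:
    """Train and score one PLSDA model per preprocessing variant.

    Every transform here is row-wise or a fixed range restriction, so
    nothing is fitted on the test set; mean-centering lives inside the
    PLSDA fit and uses training rows only.
    """
    if not variants:
        raise ValueError("need at least one preprocessing variant")
    rows = []
    for vi, spec in enumerate(variants):
        tr = apply_preprocess(train, spec)
        te = apply_preprocess(test, spec)
        model = train_plsda(tr, k_max=k_max,
                            leave_out_fraction=leave_out_fraction,
                            n_splits=n_splits, f_alpha=f_alpha,
                            seed=seed + vi)
        pred = predict_class(model, te.absorbance)
        counts = confusion_matrix(te.labels, pred, model.classes)
        acc = total_accuracy(counts)
        rows.append(VariantResult(
            spec=spec, model=model, counts=counts,
            n_wrong=counts.total - int(np.trace(counts.matrix)),
            accuracy=acc,
            sens={c: sensitivity(counts, c) for c in counts.classes},
            spec_={c: specificity(counts, c) for c in counts.classes}))
    return EvaluationReport(rows)
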