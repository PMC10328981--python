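"""Scoring detections against beat annotations with tolerance margins.

Detected critical points are matched one-to-one to annotated beat
locations, keeping only pairs within the tolerance (inclusive); the
assignment maximises the number of matched pairs and, among maximal
assignments, minimises the total time error (solved as a rectangular
assignment problem).  Matched pairs are true positives, unmatched
detections false positives, unmatched annotations false negatives.  From
the counts the usual event-detection metrics are derived; the 2x2
classifier variant adds specificity for scoring the segment classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EvalResult:
    tolerance_ms: float | None
    TP: int
    FP: int
    FN: int
    TN: int | None = None

    @property
    def Se(self) -> float | None:
        d = self.TP + self.FN
        return 100.0 * self.TP / d if d else None

    @property
    def Pplus(self) -> float | None:
        d = self.TP + self.FP
        return 100.0 * self.TP / d if d else None

    @property
    def Sp(self) -> float | None:
        if self.TN is None:
            return None
        d = self.TN + self.FP
        return 100.0 * self.TN / d if d else None

    @property
    def F1(self) -> float | None:
        se, pp = self.Se, self.Pplus
        if se is None or pp is None or se + pp == 0:
            return None
        return 2 * se * pp / (se + pp)

    @property
    def Acc(self) -> float | None:
        if self.TN is not None:
            d = self.TP + self.TN + self.FP + self.FN
            return 100.0 * (self.TP + self.TN) / d if d else None
        d = self.TP + self.FP + self.FN
        return 100.0 * self.TP / d if d else None

    def as_dict(self) -> dict:
        return {"tolerance_ms": self.tolerance_ms, "TP": self.TP, "FP": self.FP,
                "FN": self.FN, "TN": self.TN, "Se": self.Se, "Pplus": self.Pplus,
                "Sp": self.Sp, "F1": self.F1, "Acc": self.Acc}


def match(detected, truth, tol_ms: float, fs: float):
    """Pair detections with annotations within ``tol_ms``.

    Returns ``(tp, fp, fn, pairs)`` where ``pairs`` is a list of
    ``(detected_index, truth_index)`` sample-position tuples.
    """
    from scipy.optimize import linear_sum_assignment

    det = np.sort(np.asarray(detected, dtype=np.int64))
    tru = np.sort(np.asarray(truth, dtype=np.int64))
    tol = tol_ms * fs / 1000.0
    if det.size == 0 or tru.size == 0:
        return 0, int(det.size), int(tru.size), []
    diff = np.abs(det[:, None] - tru[None, :]).astype(float)
    # out-of-tolerance pairs cost more than every in-tolerance pair combined,
    # so the assignment first maximises matches, then minimises total error
    big = tol * (det.size + tru.size + 1) + 1.0
    cost = np.where(diff <= tol, diff, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(det[r]), int(tru[c])) for r, c in zip(rows, cols)
             if diff[r, c] <= tol]
    tp = len(pairs)
    return tp, int(det.size - tp), int(tru.size - tp), pairs


def detection_metrics(TP: int, FP: int, FN: int,
                      tolerance_ms: float | None = None) -> EvalResult:
    """Se, +P, F1 and accuracy (TP/(TP+FP+FN); no TN exists for events)."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    return EvalResult(tolerance_ms=tolerance_ms, TP=TP, FP=FP, FN=FN)


def classifier_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalResult:
    """Metrics for the binary VB/NVB classifier (VB is the positive class)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    return EvalResult(tolerance_ms=None, TP=tp, FP=fp, FN=fn, TN=tn)


def evaluate_record(detected, truth, fs: float,
                    tolerances_ms=(25.0, 50.0, 75.0)) -> list[EvalResult]:
    out = []
    for tol in tolerances_ms:
        tp, fp, fn, _ = match(detected, truth, tol, fs)
        out.append(detection_metrics(tp, fp, fn, tolerance_ms=tol))
    return out


def per_record_report(record_results: dict[str, list[EvalResult]]) -> pd.DataFrame:
    """One row per record (counts + metrics per tolerance), plus Total and
    Average rows; totals sum the counts, averages are unweighted means of
    the per-record percentages."""
    rows = []
    for rec_id, results in record_results.items():
        row: dict = {"record": rec_id}
        for r in results:
            tag = f"{r.tolerance_ms:g}ms"
            row[f"annotated"] = r.TP + r.FN
            row[f"detected"] = r.TP + r.FP
            row[f"TP_{tag}"] = r.TP
            row[f"FP_{tag}"] = r.FP
            row[f"Acc_{tag}"] = r.Acc
            row[f"Pplus_{tag}"] = r.Pplus
        rows.append(row)
    df = pd.DataFrame(rows)
    num = df.drop(columns=["record"])
    count_cols = [c for c in num.columns
                  if c.split("_")[0] in ("annotated", "detected", "TP", "FP")]
    metric_cols = [c for c in num.columns if c not in count_cols]
    total = {"record": "Total", **num[count_cols].sum().to_dict()}
    avg = {"record": "Average", **num[metric_cols].mean().to_dict()}
    return pd.concat([df, pd.DataFrame([total, avg])], ignore_index=True)
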