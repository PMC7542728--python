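"""Segmentation quality metrics and paired nonparametric comparison.

Per chamber and frame: the Dice coefficient 2|A∩B|/(|A|+|B|) and the percent
area variation |area(pred) − area(truth)| / area(truth).  Two models evaluated
on a common test set are compared per chamber and metric with the two-sided
Wilcoxon signed-rank test on the paired per-frame values, and summarized as
median [IQR] rows (one per view × chamber × metric), the shape of a standard
segmentation-accuracy comparison table.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, EmptyDatasetError, ShapeMismatchError

QUARTILE_CONVENTION = "linear interpolation (numpy percentile, inclusive)"


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap metric in [0, 1]; two empty masks count as a perfect match."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def percent_area_variation(pred: np.ndarray, truth: np.ndarray) -> float:
    """|area(pred) − area(truth)| / area(truth); truth must be non-empty."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"mask shapes differ: {p.shape} vs {t.shape}")
    t_area = int(t.sum())
    if t_area == 0:
        raise DegenerateInputError("truth mask is empty; ratio undefined")
    return abs(int(p.sum()) - t_area) / t_area


def paired_wilcoxon(x, y, test: str = "signed_rank") -> float:
    """Two-sided p-value for paired samples.

    The paired design calls for the signed-rank test: zero differences are
    dropped, tied absolute differences get average ranks, the exact null
    distribution is used for n <= 25 and the tie-corrected normal
    approximation beyond.  The unpaired rank-sum test is available behind
    ``test='rank_sum'`` for completeness.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeMismatchError("paired vectors must have equal length")
    if x.size < 6:
        raise ValueError("need at least 6 paired observations")
    if test == "rank_sum":
        return float(sps.ranksums(x, y).pvalue)
    if test != "signed_rank":
        raise ValueError(f"unknown test {test!r}")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = np.abs(d)
    has_ties = np.unique(ranks).size < ranks.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       correction=False, method=method)
    return float(res.pvalue)


@dataclass
class SummaryStat:
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:
        return f"{self.median:.3f} [{self.q1:.3f}-{self.q3:.3f}]"


def median_iqr(values) -> SummaryStat:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyDatasetError("cannot summarize an empty vector")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SummaryStat(float(med), float(q1), float(q3))


@dataclass
class ComparisonRow:
    view: str
    chamber: str
    metric: str                 # "dice" | "percent_variation"
    a: SummaryStat
    b: SummaryStat
    p_value: float | None
    n: int
    degenerate: bool = False    # all paired differences were zero


@dataclass
class ComparisonReport:
    """Per-view, per-chamber medians [IQR] for two models plus paired p-values."""

    rows: list[ComparisonRow] = field(default_factory=list)
    label_a: str = "model_a"
    label_b: str = "model_b"
    quartile_convention: str = QUARTILE_CONVENTION

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "quartile_convention": self.quartile_convention,
            "rows": [asdict(r) for r in self.rows],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["view", "chamber", "metric", "medianA", "q1A", "q3A",
                        "medianB", "q1B", "q3B", "p_value", "n"])
            for r in self.rows:
                w.writerow([r.view, r.chamber, r.metric,
                            r.a.median, r.a.q1, r.a.q3,
                            r.b.median, r.b.q1, r.b.q3,
                            "" if r.p_value is None else r.p_value, r.n])


def compare_training_sources(model_a, model_b, test_pairs: list,
                             label_a: str = "synthetic-trained",
                             label_b: str = "patient-trained") -> ComparisonReport:
    """Evaluate two segmentation models on a common held-out set.

    For every chamber of the models' view and both metrics, per-frame paired
    values are computed against the ground-truth masks; frames whose truth
    lacks the chamber are excluded from that chamber's rows.  Comparisons where
    every paired difference is zero are flagged degenerate (p-value None).
    """
    from .unet import predict_segmentation

    if len(test_pairs) < 6:
        raise EmptyDatasetError("need at least 6 test frames for comparison")
    if model_a.view != model_b.view:
        raise ValueError("models segment different views")
    view = model_a.view
    chambers = model_a.chambers

    values: dict[tuple[str, str, str], list[float]] = {}
    for image, truth in test_pairs:
        pred_a = predict_segmentation(model_a, image)
        pred_b = predict_segmentation(model_b, image)
        for chamber in chambers:
            t = truth.get(chamber)
            if t is None or not np.any(t):
                continue
            for label, pred in (("a", pred_a), ("b", pred_b)):
                m = pred[chamber]
                values.setdefault((chamber, "dice", label), []).append(
                    dice_coefficient(m, t))
                values.setdefault((chamber, "percent_variation", label),
                                  []).append(percent_area_variation(m, t))

    report = ComparisonReport(label_a=label_a, label_b=label_b)
    for chamber in chambers:
        for metric in ("dice", "percent_variation"):
            va = values.get((chamber, metric, "a"), [])
            vb = values.get((chamber, metric, "b"), [])
            if not va:
                continue
            degenerate = False
            try:
                p = paired_wilcoxon(va, vb)
            except DegenerateInputError:
                p, degenerate = None, True
            report.rows.append(ComparisonRow(
                view=view, chamber=chamber, metric=metric,
                a=median_iqr(va), b=median_iqr(vb), p_value=p,
                n=len(va), degenerate=degenerate))
    return report
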