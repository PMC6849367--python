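"""Confusion metrics, ROC/AUROC, and stratified cross-validation.

Metrics follow the standard confusion-matrix definitions with the positive
class = 1:

    SN  = TP / (TP + FN)          (sensitivity, recall on positives)
    SP  = TN / (TN + FP)          (specificity)
    ACC = (TP + TN) / total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

MCC is defined as 0 when its denominator vanishes.  AUROC is computed both
as the Mann-Whitney statistic (ties counted 1/2) and as the trapezoidal
area under the ROC points; the two are asserted equal.

The cross-validation harness is leakage-free: frequent patterns are mined
inside each training fold only, and the held-out fold is encoded with that
fold's feature set.  Fold assignment is seeded and invariant to input
record order (records are canonically sorted before the seeded shuffle).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import classifier as clf
from .classifier import TrainConfig
from .encoding import encode_corpus
from .errors import DegenerateRocError, LabelError, M6afgkError, StratificationError
from .mining import MiningConfig, mine_frequent
from .sequence_data import SampleRecord


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise M6afgkError("y_true and y_pred differ in length")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise LabelError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """SN, SP, ACC, MCC as fractions; NaN marks a metric with no defined
    value (e.g. SN when no positives were evaluated)."""
    if c.total == 0:
        raise M6afgkError("cannot compute metrics on zero evaluated samples")
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    acc = (c.TP + c.TN) / c.total
    denom = math.sqrt(float(c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN))
    mcc = ((c.TP * c.TN - c.FP * c.FN) / denom) if denom > 0 else 0.0
    return {"SN": sn, "SP": sp, "ACC": acc, "MCC": mcc}


def _check_two_classes(y_true: np.ndarray) -> None:
    if len(np.unique(y_true)) < 2:
        raise DegenerateRocError("ROC/AUROC need both classes present")


def roc(y_true: Sequence[int], scores: Sequence[float]) -> list[tuple[float, float]]:
    """(FPR, TPR) points from sweeping the threshold over distinct scores.

    Tied scores are grouped; the curve starts at (0,0) and ends at (1,1).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(y_true)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(y_sorted):
        j = i
        while j < len(y_sorted) and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += int(j - i - y_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def auroc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve.

    Computed by the Mann-Whitney rank formulation (ties 1/2) and by the
    trapezoid rule over :func:`roc`; the identity between the two is
    asserted before returning.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(y_true)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    mw = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pts = roc(y_true, scores)
    trap = sum((x1 - x0) * (y0 + y1) / 2
               for (x0, y0), (x1, y1) in zip(pts, pts[1:]))
    assert abs(mw - trap) < 1e-10, "rank and trapezoid AUROC disagree"
    return float(mw)


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: dict[str, float]
    auroc: float
    n_features: int
    test_ids: list[str] = field(default_factory=list)


@dataclass
class MetricsReport:
    """Per-fold and aggregate CV results.

    Aggregates are reported under both rules — metrics of the pooled
    confusion counts / pooled scores, and the mean of per-fold metrics —
    because published benchmark tables rarely state which was used.
    """

    folds: list[FoldResult]
    pooled_counts: ConfusionCounts
    pooled_metrics: dict[str, float]
    pooled_auroc: float
    mean_metrics: dict[str, float]
    mean_auroc: float
    roc_points: list[tuple[float, float]]
    seed: int
    mining_config: MiningConfig
    train_config: TrainConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "mining_config": asdict(self.mining_config),
            "train_config": asdict(self.train_config),
            "pooled": {"counts": asdict(self.pooled_counts),
                       **self.pooled_metrics, "AUROC": self.pooled_auroc},
            "fold_mean": {**self.mean_metrics, "AUROC": self.mean_auroc},
            "folds": [
                {"fold": f.fold, "counts": asdict(f.counts), **f.metrics,
                 "AUROC": f.auroc, "n_features": f.n_features}
                for f in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        cols = ["row", "TP", "TN", "FP", "FN", "SN", "SP", "ACC", "MCC", "AUROC"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for f in self.folds:
                c, m = f.counts, f.metrics
                fh.write(f"fold_{f.fold}\t{c.TP}\t{c.TN}\t{c.FP}\t{c.FN}\t"
                         f"{m['SN']:.6f}\t{m['SP']:.6f}\t{m['ACC']:.6f}\t"
                         f"{m['MCC']:.6f}\t{f.auroc:.6f}\n")
            c, m = self.pooled_counts, self.pooled_metrics
            fh.write(f"pooled\t{c.TP}\t{c.TN}\t{c.FP}\t{c.FN}\t"
                     f"{m['SN']:.6f}\t{m['SP']:.6f}\t{m['ACC']:.6f}\t"
                     f"{m['MCC']:.6f}\t{self.pooled_auroc:.6f}\n")
            m = self.mean_metrics
            fh.write(f"fold_mean\t-\t-\t-\t-\t"
                     f"{m['SN']:.6f}\t{m['SP']:.6f}\t{m['ACC']:.6f}\t"
                     f"{m['MCC']:.6f}\t{self.mean_auroc:.6f}\n")

    def write_roc_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("FPR\tTPR\n")
            for x, y in self.roc_points:
                fh.write(f"{x!r}\t{y!r}\n")


def stratified_folds(records: Sequence[SampleRecord], folds: int,
                     seed: int) -> list[list[int]]:
    """Seeded stratified partition into `folds` test index lists.

    Records are canonically sorted before the seeded shuffle, so fold
    membership depends only on record content and the seed, not on the
    order records were supplied in.
    """
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].label, records[i].id,
                                  records[i].sequence))
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {0: [], 1: []}
    for i in order:
        by_class[records[i].label].append(i)
    assignments: list[list[int]] = [[] for _ in range(folds)]
    for label, idxs in sorted(by_class.items()):
        if 0 < len(idxs) < folds:
            raise StratificationError(
                f"class {label} has {len(idxs)} members < {folds} folds"
            )
        idxs = list(np.array(idxs)[rng.permutation(len(idxs))])
        for pos, i in enumerate(idxs):
            assignments[pos % folds].append(int(i))
    return assignments


def cross_validate(records: Sequence[SampleRecord],
                   mining: MiningConfig | None = None,
                   train: TrainConfig | None = None,
                   folds: int = 10,
                   seed: int = 0) -> MetricsReport:
    """Leakage-free stratified k-fold CV of the full mine-encode-fit pipeline."""
    mining = mining or MiningConfig()
    train = train or TrainConfig()
    test_sets = stratified_folds(records, folds, seed)
    fold_results: list[FoldResult] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores: list[float] = []
    all_true: list[int] = []
    for fold_i, test_idx in enumerate(test_sets):
        test_mask = np.zeros(len(records), dtype=bool)
        test_mask[test_idx] = True
        train_recs = [r for r, m in zip(records, test_mask) if not m]
        test_recs = [r for r, m in zip(records, test_mask) if m]
        if mining.corpus_scope == "positives":
            mine_seqs = [r.sequence for r in train_recs if r.label == 1]
        else:
            mine_seqs = [r.sequence for r in train_recs]
        features = mine_frequent(mine_seqs, mining)
        X_train, y_train = encode_corpus(train_recs, features)
        X_test, y_test = encode_corpus(test_recs, features)
        model = clf.fit(X_train, y_train, train,
                        feature_fingerprint=features.fingerprint)
        y_pred, scores = clf.predict(model, X_test)
        counts = confusion(y_test, y_pred)
        fold_results.append(FoldResult(
            fold=fold_i,
            counts=counts,
            metrics=metrics(counts),
            auroc=auroc(y_test, scores),
            n_features=len(features),
            test_ids=[r.id for r in test_recs],
        ))
        pooled = pooled + counts
        all_scores.extend(scores)
        all_true.extend(y_test)
    mean_m = {k: float(np.mean([f.metrics[k] for f in fold_results]))
              for k in ("SN", "SP", "ACC", "MCC")}
    return MetricsReport(
        folds=fold_results,
        pooled_counts=pooled,
        pooled_metrics=metrics(pooled),
        pooled_auroc=auroc(all_true, all_scores),
        mean_metrics=mean_m,
        mean_auroc=float(np.mean([f.auroc for f in fold_results])),
        roc_points=roc(all_true, all_scores),
        seed=seed,
        mining_config=mining,
        train_config=train,
    )
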