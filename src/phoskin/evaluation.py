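"""Evaluation metrics with per-kinase and family/group stratified reporting.

AUC-ROC and AUC-PRC are computed over the positive vs hard-negative test
pairs only; the separate easy-negative test set is scored solely by the
false-positive rate at a probability threshold, guarding against inflated
performance on trivially rejectable peptides.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .records import KinaseRecord, LabeledPair, PairLabel

logger = logging.getLogger(__name__)

DEFAULT_FPR_THRESHOLD = 0.5


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float = DEFAULT_FPR_THRESHOLD

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self.tpr


def confusion_counts(
    scores: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_FPR_THRESHOLD
) -> ConfusionCounts:
    scores, labels = np.asarray(scores), np.asarray(labels).astype(bool)
    pred = scores > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
        threshold=threshold,
    )


def _check_binary(labels: np.ndarray, need_both: bool) -> None:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if need_both and (labels.min() == labels.max()):
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals the Mann-Whitney concordance
    probability with ties counted one half."""
    labels = np.asarray(labels)
    _check_binary(labels, need_both=True)
    return float(roc_auc_score(labels, np.asarray(scores)))

def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the step-wise (non-interpolated) precision-recall curve,
    summed over all distinct score thresholds."""
    labels = np.asarray(labels)
    _check_binary(labels, need_both=False)
    if labels.sum() == 0:
        raise ValueError("at least one positive is required")
    return float(average_precision_score(labels, np.asarray(scores)))


def fpr(scores: Sequence[float], threshold: float = DEFAULT_FPR_THRESHOLD) -> float:
    """Fraction of (all-negative) scores above the threshold."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score array")
    return float(np.mean(scores > threshold))


@dataclass
class MetricReport:
    overall_roc_auc: float
    overall_pr_auc: float
    mean_kinase_roc_auc: float
    mean_kinase_pr_auc: float
    per_kinase: dict[str, dict[str, float]] = field(default_factory=dict)
    per_family: dict[str, dict[str, float]] = field(default_factory=dict)
    per_group: dict[str, dict[str, float]] = field(default_factory=dict)
    easy_negative_fpr: float | None = None
    n_pairs: int = 0
    n_easy_negatives: int = 0
    skipped_kinases: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=float))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stratum\tname\troc_auc\tpr_auc\tn\n")
            fh.write(
                f"overall\t-\t{self.overall_roc_auc:.6f}\t{self.overall_pr_auc:.6f}\t{self.n_pairs}\n"
            )
            for level, table in (
                ("kinase", self.per_kinase),
                ("family", self.per_family),
                ("group", self.per_group),
            ):
                for name, vals in sorted(table.items()):
                    fh.write(
                        f"{level}\t{name}\t{vals['roc_auc']:.6f}\t{vals['pr_auc']:.6f}\t"
                        f"{int(vals['n'])}\n"
                    )


def stratified_report(
    scores: Sequence[float],
    pairs: Sequence[LabeledPair],
    kinome: Mapping[str, KinaseRecord],
    easy_scores: Sequence[float] | None = None,
    fpr_threshold: float = DEFAULT_FPR_THRESHOLD,
) -> MetricReport:
    """Per-kinase AUCs on positives vs paired hard negatives, averaged
    (unweighted) into family and group strata; overall AUCs pool all pairs.

    Easy negatives must arrive separately via ``easy_scores``; they enter
    only the FPR, never an AUC. Kinases lacking a positive or a negative
    are skipped with a log line.
    """
    scores = np.asarray(scores)
    if len(scores) != len(pairs):
        raise ValueError("one score per pair is required")
    if any(p.label is PairLabel.EASY_NEGATIVE for p in pairs):
        raise ValueError("easy negatives must not enter AUC computation")
    labels = np.array([1 if p.label is PairLabel.POSITIVE else 0 for p in pairs])

    report = MetricReport(
        overall_roc_auc=roc_auc(scores, labels),
        overall_pr_auc=pr_auc(scores, labels),
        mean_kinase_roc_auc=np.nan,
        mean_kinase_pr_auc=np.nan,
        n_pairs=len(pairs),
    )

    by_kinase: dict[str, list[int]] = {}
    for i, p in enumerate(pairs):
        by_kinase.setdefault(p.kinase_id, []).append(i)
    family_members: dict[str, list[str]] = {}
    group_members: dict[str, list[str]] = {}
    for kid in sorted(by_kinase):
        idx = np.array(by_kinase[kid])
        k_labels = labels[idx]
        if k_labels.min() == k_labels.max():
            logger.info("kinase %s skipped: single-class test pairs", kid)
            report.skipped_kinases.append(kid)
            continue
        report.per_kinase[kid] = {
            "roc_auc": roc_auc(scores[idx], k_labels),
            "pr_auc": pr_auc(scores[idx], k_labels),
            "n": float(len(idx)),
        }
        rec = kinome.get(kid)
        if rec is not None and rec.family:
            family_members.setdefault(rec.family, []).append(kid)
        if rec is not None and rec.group:
            group_members.setdefault(rec.group, []).append(kid)

    if report.per_kinase:
        report.mean_kinase_roc_auc = float(
            np.mean([v["roc_auc"] for v in report.per_kinase.values()])
        )
        report.mean_kinase_pr_auc = float(
            np.mean([v["pr_auc"] for v in report.per_kinase.values()])
        )
    for members, table in ((family_members, report.per_family), (group_members, report.per_group)):
        for name, kids in members.items():
            table[name] = {
                "roc_auc": float(np.mean([report.per_kinase[k]["roc_auc"] for k in kids])),
                "pr_auc": float(np.mean([report.per_kinase[k]["pr_auc"] for k in kids])),
                "n": float(len(kids)),
            }

    if easy_scores is not None:
        report.easy_negative_fpr = fpr(easy_scores, fpr_threshold)
        report.n_easy_negatives = len(easy_scores)
    return report
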