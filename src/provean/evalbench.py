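"""Evaluation machinery for labeled score sets.

Deleterious is the positive class and is called at ``score <= threshold``,
so *lower* scores rank as more positive throughout (AUC orientation
included).  Balanced accuracy is the simple average of sensitivity and
specificity; the operating threshold is chosen to maximize the minimum of
sensitivity and specificity ("balanced separation").
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .align import GapPenalties, SubstitutionMatrix
from .homologs import build_supporting_set
from .score import ProveanScorer
from .seqvar import ProteinSequence, VariantLabel, VariantRecord

__all__ = [
    "LabeledScore",
    "EvalReport",
    "UndefinedMetricError",
    "balanced_accuracy",
    "confusion",
    "select_threshold",
    "roc_auc",
    "roc_points",
    "parameter_sweep",
    "dataset_summary",
    "DatasetSummary",
    "read_labeled_scores",
    "write_labeled_scores",
]


class UndefinedMetricError(ValueError):
    """Sensitivity/specificity need both classes present."""


@dataclass(frozen=True)
class LabeledScore:
    score: float
    label: VariantLabel

    def __post_init__(self) -> None:
        if self.label not in (VariantLabel.DELETERIOUS, VariantLabel.NEUTRAL):
            raise ValueError(f"label must be binary, got {self.label}")


@dataclass(frozen=True)
class EvalReport:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    balanced_accuracy: float  # percent
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Simple average of sensitivity and specificity (both in percent)."""
    return (sensitivity + specificity) / 2.0


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    dele = np.array([s.score for s in scores if s.label is VariantLabel.DELETERIOUS])
    neut = np.array([s.score for s in scores if s.label is VariantLabel.NEUTRAL])
    if len(dele) == 0 or len(neut) == 0:
        raise UndefinedMetricError(
            f"both classes required (got {len(dele)} deleterious, {len(neut)} neutral)"
        )
    return dele, neut


def _sens_spec(dele: np.ndarray, neut: np.ndarray, threshold: float) -> tuple[float, float]:
    sens = float(np.count_nonzero(dele <= threshold)) / len(dele) * 100.0
    spec = float(np.count_nonzero(neut > threshold)) / len(neut) * 100.0
    return sens, spec


def confusion(scores: Sequence[LabeledScore], threshold: float) -> EvalReport:
    """Confusion metrics at a threshold (positive call: score <= threshold)."""
    dele, neut = _split(scores)
    tp = int(np.count_nonzero(dele <= threshold))
    fn = len(dele) - tp
    tn = int(np.count_nonzero(neut > threshold))
    fp = len(neut) - tn
    sens = tp / (tp + fn) * 100.0
    spec = tn / (tn + fp) * 100.0
    return EvalReport(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        auc=roc_auc(scores),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def _candidates(dele: np.ndarray, neut: np.ndarray) -> np.ndarray:
    distinct = np.unique(np.concatenate([dele, neut]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def select_threshold(scores: Sequence[LabeledScore]) -> float:
    """Threshold maximizing min(sensitivity, specificity).

    Candidates are midpoints between adjacent distinct scores plus one point
    below and above all scores.  Ties are broken by higher balanced accuracy,
    then by the largest threshold.
    """
    dele, neut = _split(scores)
    best: tuple[float, float, float] | None = None
    for t in _candidates(dele, neut):
        sens, spec = _sens_spec(dele, neut, t)
        key = (min(sens, spec), balanced_accuracy(sens, spec), t)
        if best is None or key > best:
            best = key
    assert best is not None
    return float(best[2])


def roc_auc(scores: Sequence[LabeledScore]) -> float:
    """AUC with deleterious ranked by lower score; ties count half."""
    _split(scores)  # validates both classes present
    y = [s.label is VariantLabel.DELETERIOUS for s in scores]
    return float(roc_auc_score(y, [-s.score for s in scores]))


def roc_points(scores: Sequence[LabeledScore]) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the ROC curve, for plotting/export."""
    _split(scores)
    y = [s.label is VariantLabel.DELETERIOUS for s in scores]
    fpr, tpr, _ = roc_curve(y, [-s.score for s in scores])
    return list(zip(map(float, fpr), map(float, tpr)))


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

def parameter_sweep(gap_penalty_pairs: Sequence[tuple[int, int]],
                    identity_thresholds: Sequence[float],
                    cluster_counts: Sequence[int],
                    problems: Sequence[tuple[ProteinSequence,
                                             Sequence[ProteinSequence],
                                             Sequence[VariantRecord]]],
                    matrix: SubstitutionMatrix | None = None,
                    ) -> list[dict]:
    """Balanced accuracy for every grid cell, re-scoring all labeled variants.

    ``problems`` is a list of (query, homologs, labeled variant records); each
    cell's scores are pooled across problems, the balanced-separation
    threshold is selected on them, and the balanced accuracy at that threshold
    is reported.  Rows come out in ``itertools.product`` order of the three
    axes; the grid size is the product of the axis lengths.

    Clusterings are shared across cluster counts (taking the top-k clusters of
    a ranking equals rebuilding with ``max_clusters = k``), so the heavy
    alignment work scales with ``len(gap_penalty_pairs) * len(identity_thresholds)``.
    """
    matrix = matrix if matrix is not None else SubstitutionMatrix.load()
    if not problems:
        raise ValueError("no labeled problems supplied")
    max_k = max(cluster_counts)
    rows: list[dict] = []
    for (g_open, g_extend), ident in itertools.product(gap_penalty_pairs,
                                                       identity_thresholds):
        gaps = GapPenalties(open=g_open, extend=g_extend)
        # per problem: ordered cluster-mean vectors for every labeled variant
        prepared: list[tuple[list[tuple[float, ...]], list[VariantLabel]]] = []
        for query, homologs, records in problems:
            sset = build_supporting_set(query, homologs, identity_threshold=ident,
                                        max_clusters=max_k, matrix=matrix, gaps=gaps)
            scorer = ProveanScorer(query, sset, matrix=matrix, gaps=gaps)
            means = [
                tuple(float(np.mean(c)) for c in scorer.delta_scores(rec.variant))
                for rec in records
            ]
            prepared.append((means, [rec.label for rec in records]))
        by_count: dict[int, dict] = {}
        for k in cluster_counts:
            if k in by_count:
                rows.append(dict(by_count[k]))
                continue
            pooled = [
                LabeledScore(float(np.mean(m[:k])), label)
                for means, labels in prepared
                for m, label in zip(means, labels)
            ]
            t = select_threshold(pooled)
            report = confusion(pooled, t)
            by_count[k] = {
                "gap_open": g_open,
                "gap_extend": g_extend,
                "identity_threshold": ident,
                "max_clusters": k,
                "threshold": t,
                "balanced_accuracy": report.balanced_accuracy,
                "auc": report.auc,
            }
            rows.append(by_count[k])
    return rows


# ---------------------------------------------------------------------------
# Dataset summary utility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSummary:
    row_totals: dict[str, int]
    column_totals: dict[str, int]
    grand_total: int


def dataset_summary(table: Mapping[str, Mapping[str, int]]) -> DatasetSummary:
    """Marginal totals of a counts cross-tab (rows x columns of counts)."""
    row_totals = {r: int(sum(cols.values())) for r, cols in table.items()}
    column_totals: dict[str, int] = {}
    for cols in table.values():
        for c, n in cols.items():
            column_totals[c] = column_totals.get(c, 0) + int(n)
    return DatasetSummary(
        row_totals=row_totals,
        column_totals=column_totals,
        grand_total=sum(row_totals.values()),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_labeled_scores(path: Union[str, Path]) -> list[LabeledScore]:
    """TSV with columns score, label (deleterious|neutral); '#' comments ignored."""
    out: list[LabeledScore] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected columns score, label")
            out.append(LabeledScore(float(parts[0]), VariantLabel(parts[1].strip().lower())))
    return out


def write_labeled_scores(scores: Iterable[LabeledScore], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in scores:
            writer.writerow([f"{s.score:.6g}", s.label.value])


def write_roc_csv(scores: Sequence[LabeledScore], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["fpr", "tpr"])
        writer.writerows(roc_points(scores))


def write_sweep_tsv(rows: Sequence[dict], path: Union[str, Path]) -> None:
    if not rows:
        raise ValueError("empty sweep result")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
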