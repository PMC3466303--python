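"""Delta scores, cluster-averaged final scores, classification, saturation scan.

The delta score of a variant v against a subject S is
``semiglobal_score(Q', S) - semiglobal_score(Q, S)`` where Q' is the query
with v applied.  Deltas are averaged within each cluster of the supporting
set, then across clusters with equal weight per cluster; a variant is called
deleterious when this final score falls at or below the threshold
(default -2.282, inclusive).

:class:`ProveanScorer` caches the base scores S(Q, subject) so that batch
scoring and the saturation scan compute each base alignment exactly once;
results are identical to naive per-variant recomputation.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .align import GapPenalties, SubstitutionMatrix, semiglobal_score
from .homologs import SupportingSequenceSet
from .seqvar import (
    AA20,
    ProteinSequence,
    Variant,
    VariantKind,
    apply_variant,
    format_variant,
    null_variant,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "Prediction",
    "ProveanResult",
    "ProveanScorer",
    "SaturationScan",
    "classify",
    "delta_score",
    "provean_score",
    "saturation_scan",
    "unbiased_average",
]

DEFAULT_THRESHOLD = -2.282


class Prediction(enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class ProveanResult:
    """Final score for one variant: equal-weight mean of cluster mean deltas."""

    variant: Variant
    score: float
    cluster_means: tuple[float, ...]
    n_clusters: int
    n_sequences: int
    prediction: Prediction
    threshold: float = DEFAULT_THRESHOLD


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> Prediction:
    """Deleterious iff ``score <= threshold`` (boundary inclusive)."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    return Prediction.DELETERIOUS if score <= threshold else Prediction.NEUTRAL


def delta_score(query: ProteinSequence, variant: Variant, subject: ProteinSequence,
                matrix: SubstitutionMatrix | None = None,
                gaps: GapPenalties | None = None) -> int:
    """Change in semi-global alignment score to ``subject`` caused by ``variant``."""
    mutated = apply_variant(query, variant)
    return (semiglobal_score(mutated, subject, matrix, gaps)
            - semiglobal_score(query, subject, matrix, gaps))


def unbiased_average(cluster_deltas: Sequence[Sequence[float]]) -> tuple[float, tuple[float, ...]]:
    """Equal-cluster-weight average: mean over clusters of within-cluster means.

    Returns ``(final_score, cluster_means)``.  Cluster sizes do not weight the
    final score: deltas {-6, -6, 0} and {+3} give means (-4, +3) and a final
    score of -0.5, not the size-weighted -2.25.
    """
    if not cluster_deltas or any(len(c) == 0 for c in cluster_deltas):
        raise ValueError("every cluster must contribute at least one delta")
    means = tuple(float(np.mean(np.asarray(c, dtype=np.float64))) for c in cluster_deltas)
    return float(np.mean(means)), means


class ProveanScorer:
    """Scores variants of one query against a fixed supporting set.

    Base alignment scores S(Q, subject) are computed once at construction and
    reused for every variant (the variant side S(Q', subject) is what changes).
    """

    def __init__(self, query: ProteinSequence, supporting_set: SupportingSequenceSet,
                 matrix: SubstitutionMatrix | None = None,
                 gaps: GapPenalties | None = None,
                 threshold: float = DEFAULT_THRESHOLD):
        self.query = query
        self.supporting_set = supporting_set
        self.matrix = matrix if matrix is not None else SubstitutionMatrix.load()
        self.gaps = gaps if gaps is not None else GapPenalties()
        self.threshold = threshold
        self._base: list[list[int]] = [
            [semiglobal_score(query, s, self.matrix, self.gaps) for s in c.members]
            for c in supporting_set.clusters
        ]

    def delta_scores(self, variant: Variant) -> list[list[int]]:
        """Per-cluster lists of integer deltas for one variant."""
        variant.validate_against(self.query)
        if variant.is_null:
            return [[0] * len(base) for base in self._base]
        mutated = apply_variant(self.query, variant)
        return [
            [semiglobal_score(mutated, s, self.matrix, self.gaps) - b
             for s, b in zip(c.members, base)]
            for c, base in zip(self.supporting_set.clusters, self._base)
        ]

    def score(self, variant: Variant) -> ProveanResult:
        final, means = unbiased_average(self.delta_scores(variant))
        return ProveanResult(
            variant=variant,
            score=final,
            cluster_means=means,
            n_clusters=self.supporting_set.n_clusters,
            n_sequences=self.supporting_set.n_sequences,
            prediction=classify(final, self.threshold),
            threshold=self.threshold,
        )

    def score_many(self, variants: Iterable[Variant]) -> list[ProveanResult]:
        return [self.score(v) for v in variants]

    def saturation_scan(self) -> "SaturationScan":
        """Scores for every single substitution, deletion, and insertion.

        One row per query position; 41 columns: the 20 substitutions (the
        self-substitution column is identically 0), the single-residue
        deletion, and the 20 single-residue insertions (inserted after the
        row's position).
        """
        L = len(self.query)
        labels = [f"sub:{aa}" for aa in AA20] + ["del"] + [f"ins:{aa}" for aa in AA20]
        values = np.zeros((L, len(labels)), dtype=np.float64)
        for pos in range(1, L + 1):
            ref = self.query.residue(pos)
            row = []
            for aa in AA20:
                if aa == ref:
                    row.append(0.0)
                else:
                    row.append(self.score(Variant(VariantKind.SUBSTITUTION, pos, ref, aa)).score)
            if L > 1:
                row.append(self.score(Variant(VariantKind.DELETION, pos, ref, "")).score)
            else:  # deleting the only residue is undefined
                row.append(float("nan"))
            for aa in AA20:
                row.append(self.score(Variant(VariantKind.INSERTION, pos, "", aa)).score)
            values[pos - 1] = row
        return SaturationScan(query=self.query, column_labels=tuple(labels), values=values)


def provean_score(query: ProteinSequence, variant: Variant,
                  supporting_set: SupportingSequenceSet,
                  matrix: SubstitutionMatrix | None = None,
                  gaps: GapPenalties | None = None,
                  threshold: float = DEFAULT_THRESHOLD) -> ProveanResult:
    """One-shot final score for a single variant (see :class:`ProveanScorer`)."""
    return ProveanScorer(query, supporting_set, matrix, gaps, threshold).score(variant)


@dataclass(frozen=True)
class SaturationScan:
    """Position x variant-type matrix of final scores for a query."""

    query: ProteinSequence
    column_labels: tuple[str, ...]
    values: np.ndarray  # shape (len(query), 41)

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["position", "ref"] + list(self.column_labels))
            for i, row in enumerate(self.values):
                writer.writerow(
                    [i + 1, self.query.residue(i + 1)]
                    + [f"{x:.3f}" for x in row])


def saturation_scan(query: ProteinSequence, supporting_set: SupportingSequenceSet,
                    matrix: SubstitutionMatrix | None = None,
                    gaps: GapPenalties | None = None,
                    threshold: float = DEFAULT_THRESHOLD) -> SaturationScan:
    return ProveanScorer(query, supporting_set, matrix, gaps, threshold).saturation_scan()


def write_results_tsv(results: Iterable[ProveanResult], path: Union[str, Path],
                      per_cluster: bool = False) -> None:
    """Write scoring results: variant, score (3 decimals), call, set sizes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["variant", "provean_score", "prediction", "n_clusters",
                  "n_supporting_sequences"]
        if per_cluster:
            header.append("cluster_means")
        writer.writerow(header)
        for r in results:
            row = [format_variant(r.variant), f"{r.score:.3f}",
                   r.prediction.value, r.n_clusters, r.n_sequences]
            if per_cluster:
                row.append(",".join(f"{m:.3f}" for m in r.cluster_means))
            writer.writerow(row)
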