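"""Supporting sequence set construction.

Homologous hits are E-value filtered and deduplicated, then greedily
clustered at 80% identity (CD-HIT style: longest first, each sequence joins
the first cluster whose representative it matches at or above the threshold).
Clusters are ranked by alignment score of their representative against the
query, the query's own cluster first, and capped (default 45).  The query
always participates, so scoring degrades gracefully to a query-only set.

Identity between two sequences is the number of identical aligned pairs on a
best-scoring semi-global alignment divided by the length of the shorter
sequence (CD-HIT's denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .align import GapPenalties, SubstitutionMatrix, semiglobal_identity, semiglobal_score
from .seqvar import ProteinSequence

__all__ = [
    "HomologHit",
    "Cluster",
    "SupportingSequenceSet",
    "CrossReferenceError",
    "filter_hits",
    "pairwise_identity",
    "cluster_sequences",
    "build_supporting_set",
    "read_hit_table",
    "read_cdhit_clusters",
]

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.80
DEFAULT_MAX_CLUSTERS = 45
DEFAULT_E_THRESHOLD = 0.1


class CrossReferenceError(ValueError):
    """A tabular record references a sequence id absent from the FASTA."""


@dataclass(frozen=True)
class HomologHit:
    sequence: ProteinSequence
    evalue: float | None = None
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.sequence.id!r}")


@dataclass
class Cluster:
    """A redundancy group of homologs with a designated representative."""

    members: list[ProteinSequence]
    representative: ProteinSequence
    query_similarity: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster has no members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SupportingSequenceSet:
    """Clustered homologs (query included) that delta scores average over."""

    clusters: list[Cluster]
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    max_clusters: int = DEFAULT_MAX_CLUSTERS
    contains_query: bool = True

    def __post_init__(self) -> None:
        if len(self.clusters) > self.max_clusters:
            raise ValueError(
                f"{len(self.clusters)} clusters exceed cap {self.max_clusters}"
            )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_sequences(self) -> int:
        return sum(c.size for c in self.clusters)

    def sequences(self) -> Iterable[ProteinSequence]:
        for cluster in self.clusters:
            yield from cluster.members


# ---------------------------------------------------------------------------
# Hit filtering
# ---------------------------------------------------------------------------

def filter_hits(hits: Sequence[HomologHit],
                e_threshold: float = DEFAULT_E_THRESHOLD) -> list[HomologHit]:
    """Keep hits with E-value <= threshold; deduplicate identical sequences.

    Hits lacking an E-value pass the filter (logged).  Exact duplicate
    sequences keep the best (smallest) E-value.
    """
    kept: dict[str, HomologHit] = {}
    for hit in hits:
        if hit.evalue is None:
            logger.warning("hit %s has no E-value; passing filter", hit.sequence.id)
        elif hit.evalue > e_threshold:
            continue
        key = hit.sequence.residues
        prev = kept.get(key)
        if prev is None or _evalue_key(hit) < _evalue_key(prev):
            kept[key] = hit
    return list(kept.values())


def _evalue_key(hit: HomologHit) -> float:
    return float("inf") if hit.evalue is None else hit.evalue


# ---------------------------------------------------------------------------
# Identity and clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: ProteinSequence, b: ProteinSequence,
                      matrix: SubstitutionMatrix | None = None,
                      gaps: GapPenalties | None = None) -> float:
    """Fraction of identical aligned pairs over min(len(a), len(b)).

    Identities are counted on a best-scoring semi-global alignment (among
    ties, the alignment with most identities).
    """
    _, ident = semiglobal_identity(a, b, matrix, gaps)
    return ident / min(len(a.residues), len(b.residues))


def cluster_sequences(seqs: Sequence[ProteinSequence],
                      identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                      matrix: SubstitutionMatrix | None = None,
                      gaps: GapPenalties | None = None) -> list[Cluster]:
    """Greedy incremental clustering at the given identity threshold.

    Sequences are processed longest first (ties broken lexicographically by
    residues then id, for reproducibility); each joins the first existing
    cluster whose representative it matches at >= threshold, else founds a
    new cluster as its representative.  The result partitions the input.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    matrix = matrix if matrix is not None else SubstitutionMatrix.load()
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.residues, s.id))
    clusters: list[Cluster] = []
    for seq in ordered:
        for cluster in clusters:
            if pairwise_identity(seq, cluster.representative, matrix, gaps) >= identity_threshold:
                cluster.members.append(seq)
                break
        else:
            clusters.append(Cluster(members=[seq], representative=seq))
    return clusters


def build_supporting_set(query: ProteinSequence,
                         homologs: Sequence[ProteinSequence],
                         identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                         max_clusters: int = DEFAULT_MAX_CLUSTERS,
                         matrix: SubstitutionMatrix | None = None,
                         gaps: GapPenalties | None = None) -> SupportingSequenceSet:
    """Cluster query + homologs, rank clusters by similarity to the query,
    and keep at most ``max_clusters`` (the query's cluster always first).

    Exact duplicate sequences (identical residues) are dropped before
    clustering — they carry no extra evidence, and removing them makes the
    final averaged score invariant to duplicated database entries.
    """
    matrix = matrix if matrix is not None else SubstitutionMatrix.load()
    unique: dict[str, ProteinSequence] = {query.residues: query}
    dropped = 0
    for h in homologs:
        if h.residues in unique:
            dropped += 1
        else:
            unique[h.residues] = h
    if dropped:
        logger.info("dropped %d exact duplicate homolog(s)", dropped)
    clusters = cluster_sequences(list(unique.values()), identity_threshold,
                                 matrix, gaps)
    for cluster in clusters:
        cluster.query_similarity = float(
            semiglobal_score(cluster.representative, query, matrix, gaps))
    query_cluster = next(c for c in clusters if query in c.members)
    others = [c for c in clusters if c is not query_cluster]
    others.sort(key=lambda c: (-c.query_similarity, -c.size, c.representative.id))
    ranked = [query_cluster] + others
    kept = ranked[:max_clusters]
    logger.info(
        "supporting set for %s: %d clusters (%d before cap), %d sequences",
        query.id, len(kept), len(ranked), sum(c.size for c in kept))
    return SupportingSequenceSet(
        clusters=kept,
        identity_threshold=identity_threshold,
        max_clusters=max_clusters,
    )


# ---------------------------------------------------------------------------
# Upstream tool output ingestion (BLAST tabular, CD-HIT .clstr)
# ---------------------------------------------------------------------------

def read_hit_table(path: Union[str, Path],
                   sequences: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
                   ) -> list[HomologHit]:
    """Parse the standard 12-column BLAST tabular format (outfmt 6).

    Column 2 is the subject id (looked up in ``sequences``), column 11 the
    E-value, column 12 the bit score.  ``#`` comment lines are ignored.
    """
    seq_map = _as_map(sequences)
    hits: list[HomologHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            sid = parts[1]
            if sid not in seq_map:
                raise CrossReferenceError(
                    f"{path}:{lineno}: subject id {sid!r} not present in FASTA"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed E-value/bitscore fields"
                ) from None
            hits.append(HomologHit(seq_map[sid], evalue=evalue, bitscore=bitscore))
    return hits


def read_cdhit_clusters(path: Union[str, Path],
                        sequences: Mapping[str, ProteinSequence] | Sequence[ProteinSequence],
                        ) -> list[Cluster]:
    """Parse CD-HIT ``.clstr`` output into Clusters (representative = ``*`` line)."""
    seq_map = _as_map(sequences)
    clusters: list[Cluster] = []
    members: list[ProteinSequence] = []
    rep: ProteinSequence | None = None

    def flush(lineno: int) -> None:
        nonlocal members, rep
        if members:
            if rep is None:
                raise ValueError(f"{path}:{lineno}: cluster has no representative ('*')")
            clusters.append(Cluster(members=members, representative=rep))
        members, rep = [], None

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                continue
            try:
                desc = line.split(">", 1)[1]
            except IndexError:
                raise ValueError(f"{path}:{lineno}: malformed member line") from None
            sid = desc.split("...")[0].strip()
            if sid not in seq_map:
                raise CrossReferenceError(
                    f"{path}:{lineno}: sequence id {sid!r} not present in FASTA"
                )
            members.append(seq_map[sid])
            if line.rstrip().endswith("*"):
                rep = seq_map[sid]
        flush(lineno + 1)
    return clusters


def _as_map(sequences) -> Mapping[str, ProteinSequence]:
    if isinstance(sequences, Mapping):
        return sequences
    return {s.id: s for s in sequences}
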