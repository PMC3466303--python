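"""Synthetic homolog families with conserved/free position structure.

The generator is a test fixture, not a simulator of record: it produces a
random query, subfamily "ancestors" sharing substitution choices (so that
identity clustering has real structure and over-represented subfamilies can
exercise the equal-cluster-weight rule), and leaf homologs with per-position
substitutions at free positions plus optional short indels away from
conserved positions.  Conserved positions are never substituted or deleted;
with ``indel_rate = 0`` every homolog is column-identical to the query at
conserved positions.

All randomness flows through one ``numpy`` generator seeded from the model;
identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqvar import (
    AA20,
    ProteinSequence,
    Variant,
    VariantKind,
    VariantLabel,
    VariantRecord,
)

__all__ = ["FamilyModel", "generate_family", "generate_labeled_variants"]

#: probability that a substituted position uses the subfamily's shared residue
_SUBFAMILY_COHESION = 0.7
#: geometric length parameter for indels
_INDEL_GEOM_P = 0.5
_MAX_INDEL = 3


@dataclass(frozen=True)
class FamilyModel:
    length: int
    conserved_positions: frozenset[int]  # 1-based
    substitution_rate_free: float = 0.3
    indel_rate: float = 0.0
    n_homologs: int = 30
    n_subfamilies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n_homologs < 1:
            raise ValueError("n_homologs must be >= 1")
        if self.n_subfamilies < 1:
            raise ValueError("n_subfamilies must be >= 1")
        if not (0.0 <= self.substitution_rate_free <= 1.0):
            raise ValueError("substitution_rate_free must be in [0, 1]")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise ValueError("indel_rate must be in [0, 1]")
        object.__setattr__(self, "conserved_positions",
                           frozenset(self.conserved_positions))
        bad = [p for p in self.conserved_positions if not 1 <= p <= self.length]
        if bad:
            raise ValueError(f"conserved positions out of range: {sorted(bad)}")

    @property
    def free_positions(self) -> list[int]:
        return [p for p in range(1, self.length + 1)
                if p not in self.conserved_positions]


def _other_residue(rng: np.random.Generator, current: str) -> str:
    choices = [a for a in AA20 if a != current]
    return choices[rng.integers(len(choices))]


def generate_family(model: FamilyModel) -> tuple[ProteinSequence, list[ProteinSequence]]:
    """Generate ``(query, homologs)`` for a family model.

    Each homolog position that is free mutates away from the query with
    probability ``substitution_rate_free`` exactly (so expected identity to
    the query at free positions is ``1 - substitution_rate_free``); mutated
    residues are the subfamily's shared choice with probability 0.7, else an
    independent draw.  Indels (insertions or deletions of geometric length,
    capped at 3) occur at free positions with probability ``indel_rate`` and
    never remove conserved residues.
    """
    rng = np.random.default_rng(model.seed)
    aa = np.array(list(AA20))
    query_res = "".join(aa[rng.integers(0, len(aa), size=model.length)])
    query = ProteinSequence(id=f"synthfam_query_{model.seed}", residues=query_res)

    free = model.free_positions
    # subfamily-shared substitution targets, one per (subfamily, free position)
    shared = {
        (s, p): _other_residue(rng, query_res[p - 1])
        for s in range(model.n_subfamilies)
        for p in free
    }

    homologs: list[ProteinSequence] = []
    for h in range(model.n_homologs):
        sub = int(rng.integers(model.n_subfamilies))
        residues = list(query_res)
        for p in free:
            if rng.random() < model.substitution_rate_free:
                if rng.random() < _SUBFAMILY_COHESION:
                    residues[p - 1] = shared[(sub, p)]
                else:
                    residues[p - 1] = _other_residue(rng, query_res[p - 1])
        if model.indel_rate > 0:
            residues = _apply_indels(rng, residues, model)
        homologs.append(ProteinSequence(
            id=f"synthfam_hom_{model.seed}_{h}_sf{sub}",
            residues="".join(r for r in residues if r),
        ))
    return query, homologs


def _apply_indels(rng: np.random.Generator, residues: list[str],
                  model: FamilyModel) -> list[str]:
    """Mutate a residue list in place with short indels at free positions.

    Deletions blank out a run of free residues (stopping at any conserved
    position); insertions append random residues after a free position.
    Processing right-to-left keeps 1-based coordinates valid throughout.
    """
    aa = np.array(list(AA20))
    for p in range(model.length, 0, -1):
        if p in model.conserved_positions or rng.random() >= model.indel_rate:
            continue
        k = min(int(rng.geometric(_INDEL_GEOM_P)), _MAX_INDEL)
        if rng.random() < 0.5:  # deletion of up to k free residues from p
            for q in range(p, min(p + k, model.length + 1)):
                if q in model.conserved_positions:
                    break
                residues[q - 1] = ""
        else:  # insertion of k random residues after p
            residues[p - 1] = residues[p - 1] + "".join(
                aa[rng.integers(0, len(aa), size=k)])
    return residues


def generate_labeled_variants(model: FamilyModel, query: ProteinSequence,
                              n_deleterious: int, n_neutral: int,
                              seed: int | None = None,
                              kinds: Sequence[VariantKind] = (
                                  VariantKind.SUBSTITUTION,
                                  VariantKind.SUBSTITUTION,
                                  VariantKind.DELETION,
                              ),
                              homologs: Sequence[ProteinSequence] | None = None,
                              ) -> list[VariantRecord]:
    """Labeled variant records: deleterious at conserved, neutral at free positions.

    The variant kind is sampled uniformly from ``kinds`` (repeats weight the
    mix; all four kinds are accepted).  When ``homologs`` is supplied, neutral
    substitutions draw their alternate residue from residues actually observed
    among the homologs at that column (mimicking how common polymorphisms sit
    inside the family's observed variation); otherwise alternates are uniform
    over the other 19 residues.  Generated ref/alt lengths never exceed 3.
    Raises when the model lacks conserved or free positions for the requested
    counts.
    """
    if n_deleterious < 0 or n_neutral < 0:
        raise ValueError("variant counts must be non-negative")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    conserved = sorted(model.conserved_positions)
    free = model.free_positions
    if n_deleterious and not conserved:
        raise ValueError("model has no conserved positions for deleterious variants")
    if n_neutral and not free:
        raise ValueError("model has no free positions for neutral variants")

    # column residue sets from homologs that kept the query's length (those
    # columns are alignable by index)
    columns: dict[int, list[str]] = {}
    if homologs is not None:
        for p in free:
            seen = {h.residues[p - 1] for h in homologs if len(h) == len(query)}
            seen.discard(query.residue(p))
            columns[p] = sorted(seen)

    records: list[VariantRecord] = []
    for label, n, pool in ((VariantLabel.DELETERIOUS, n_deleterious, conserved),
                           (VariantLabel.NEUTRAL, n_neutral, free)):
        for _ in range(n):
            pos = pool[int(rng.integers(len(pool)))]
            kind = kinds[int(rng.integers(len(kinds)))]
            observed = columns.get(pos) if label is VariantLabel.NEUTRAL else None
            records.append(
                VariantRecord(_make_variant(rng, query, pos, kind, observed), label))
    return records


def _make_variant(rng: np.random.Generator, query: ProteinSequence,
                  pos: int, kind: VariantKind,
                  observed: Sequence[str] | None = None) -> Variant:
    ref1 = query.residue(pos)
    aa = np.array(list(AA20))
    if kind is VariantKind.SUBSTITUTION:
        if observed:
            return Variant(kind, pos, ref1, observed[int(rng.integers(len(observed)))])
        return Variant(kind, pos, ref1, _other_residue(rng, ref1))
    if kind is VariantKind.DELETION:
        if len(query) < 2:
            raise ValueError("query too short for a deletion variant")
        return Variant(kind, pos, ref1, "")
    if kind is VariantKind.INSERTION:
        k = int(rng.integers(1, 4))
        alt = "".join(aa[rng.integers(0, len(aa), size=k)])
        return Variant(kind, pos, "", alt)
    # replacement: span of up to 2 residues, alt of different content
    span = min(2, len(query) - pos + 1)
    ref = query.residues[pos - 1: pos - 1 + span]
    alt = "".join(aa[rng.integers(0, len(aa), size=span)])
    if alt == ref or (span == 1 and len(alt) == 1):
        alt = alt + _other_residue(rng, ref[-1])
    return Variant(VariantKind.REPLACEMENT, pos, ref, alt)
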