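"""Protein sequences, in-frame variants, parsing, and variant application.

Coordinates are 1-based and inclusive at the protein level.  Insertions
anchor *after* the stated position (position 0 inserts before the first
residue).  Variants longer than 6 residues are accepted with a warning —
the method is length-agnostic but was validated on short indels.
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA20",
    "ALPHABET",
    "ProteinSequence",
    "Variant",
    "VariantKind",
    "VariantLabel",
    "VariantRecord",
    "VariantSyntaxError",
    "ReferenceMismatchError",
    "parse_variant",
    "format_variant",
    "apply_variant",
    "null_variant",
    "read_fasta",
    "write_fasta",
    "read_variant_tsv",
    "write_variant_tsv",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED = "BZX"  # ambiguity codes, accepted and flagged
ALPHABET = frozenset(AA20 + EXTENDED)

#: variant lengths above this are outside the validated regime
VALIDATED_MAX_LENGTH = 6


class VariantSyntaxError(ValueError):
    """The variant string does not match the documented grammar."""


class ReferenceMismatchError(ValueError):
    """Stated reference residues disagree with the query sequence."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino acid string (query or supporting sequence)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted(set(self.residues) - ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains unsupported residues {bad}; "
                f"allowed: 20 standard amino acids plus B/Z/X"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} out of range 1..{len(self)}")
        return self.residues[position - 1]

    @property
    def has_extended(self) -> bool:
        """True when ambiguity codes (B/Z/X) are present."""
        return any(c in EXTENDED for c in self.residues)


class VariantKind(enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    REPLACEMENT = "replacement"


class VariantLabel(enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


def _infer_kind(ref: str, alt: str) -> VariantKind:
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SUBSTITUTION
    if ref and not alt:
        return VariantKind.DELETION
    if alt and not ref:
        return VariantKind.INSERTION
    if ref and alt:
        return VariantKind.REPLACEMENT
    raise ValueError("variant must change at least one residue (ref and alt both empty)")


@dataclass(frozen=True)
class Variant:
    """One in-frame protein change with 1-based coordinates.

    For insertions ``position`` means "insert ``alt`` after this residue";
    position 0 denotes an N-terminal insertion.
    """

    kind: VariantKind
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if _infer_kind(self.ref, self.alt) is not self.kind:
            raise ValueError(
                f"kind {self.kind.value!r} inconsistent with ref={self.ref!r} "
                f"alt={self.alt!r}"
            )
        if self.kind is VariantKind.INSERTION:
            if self.position < 0:
                raise ValueError("insertion position must be >= 0")
        elif self.position < 1:
            raise ValueError("position must be >= 1")
        for s in (self.ref, self.alt):
            bad = sorted(set(s) - ALPHABET)
            if bad:
                raise ValueError(f"variant contains unsupported residues {bad}")
        if max(len(self.ref), len(self.alt)) > VALIDATED_MAX_LENGTH:
            warnings.warn(
                f"variant alters {max(len(self.ref), len(self.alt))} residues; "
                f"lengths > {VALIDATED_MAX_LENGTH} are outside the validated regime",
                stacklevel=2,
            )

    @classmethod
    def make(cls, position: int, ref: str, alt: str) -> "Variant":
        """Build a variant, inferring its kind from ref/alt lengths."""
        return cls(_infer_kind(ref.upper(), alt.upper()), position, ref, alt)

    def validate_against(self, query: ProteinSequence) -> None:
        """Raise unless the variant is applicable to ``query``."""
        if self.kind is VariantKind.INSERTION:
            if self.position > len(query):
                raise ReferenceMismatchError(
                    f"insertion anchor {self.position} beyond sequence "
                    f"length {len(query)}"
                )
            return
        end = self.position + len(self.ref) - 1
        if end > len(query):
            raise ReferenceMismatchError(
                f"variant span {self.position}..{end} beyond sequence length {len(query)}"
            )
        found = query.residues[self.position - 1 : end]
        if found != self.ref:
            raise ReferenceMismatchError(
                f"reference residues {self.ref!r} at position {self.position} "
                f"do not match query residues {found!r}"
            )

    @property
    def is_null(self) -> bool:
        return self.ref == self.alt


@dataclass(frozen=True)
class VariantRecord:
    """A variant with an optional class label (evaluation contexts only)."""

    variant: Variant
    label: VariantLabel = VariantLabel.UNKNOWN


# ---------------------------------------------------------------------------
# Parsing / formatting
# ---------------------------------------------------------------------------

_AA = r"[A-Z]"
_RE_SUB = re.compile(rf"^({_AA})(\d+)({_AA})$")
_RE_DEL = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?del$")
_RE_DELINS = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?delins({_AA}+)$")
_RE_INS = re.compile(rf"^(?:({_AA})?(\d+))_(?:({_AA})?(\d+))ins({_AA}+)$")


def parse_variant(text: str, query: ProteinSequence) -> Variant:
    """Parse an HGVS-like variant string and validate it against ``query``.

    Grammar (1-based positions)::

        G12C              substitution
        F508del           single-residue deletion
        K10_L12del        multi-residue deletion
        K10_E11insGS      insertion of GS after residue 10 (flanks optional:
                          10_11insGS; 0_1insGS inserts before the first residue)
        A5_G6delinsTR     replacement (delins); A5delinsT also accepted

    Raises :class:`VariantSyntaxError` on grammar violations and
    :class:`ReferenceMismatchError` when stated residues disagree with the
    query (a coordinate or sequence-version problem).
    """
    text = text.strip()
    if m := _RE_SUB.match(text):
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        v = Variant(VariantKind.SUBSTITUTION, pos, ref, alt)
        v.validate_against(query)
        return v
    if m := _RE_DEL.match(text):
        return _parse_span(m, query, alt=None)
    if m := _RE_DELINS.match(text):
        return _parse_span(m, query, alt=m.group(5))
    if m := _RE_INS.match(text):
        left_res, left, right_res, right, alt = (
            m.group(1), int(m.group(2)), m.group(3), int(m.group(4)), m.group(5))
        if right != left + 1:
            raise VariantSyntaxError(
                f"{text!r}: insertion flanks must be adjacent (got {left} and {right})"
            )
        for res, pos in ((left_res, left), (right_res, right)):
            if res is not None:
                if not 1 <= pos <= len(query) or query.residue(pos) != res:
                    raise ReferenceMismatchError(
                        f"{text!r}: flank {res}{pos} does not match query"
                    )
        v = Variant(VariantKind.INSERTION, left, "", alt)
        v.validate_against(query)
        return v
    raise VariantSyntaxError(f"unrecognized variant string {text!r}")


def _parse_span(m: re.Match, query: ProteinSequence, alt: str | None) -> Variant:
    first_res, first = m.group(1), int(m.group(2))
    if m.group(3) is not None:
        last_res, last = m.group(3), int(m.group(4))
    else:
        last_res, last = first_res, first
    if last < first:
        raise VariantSyntaxError(f"span end {last} precedes start {first}")
    if last > len(query):
        raise ReferenceMismatchError(
            f"span {first}..{last} beyond sequence length {len(query)}"
        )
    ref = query.residues[first - 1 : last]
    if ref[0] != first_res or ref[-1] != last_res:
        raise ReferenceMismatchError(
            f"stated residues {first_res}{first}..{last_res}{last} do not match "
            f"query residues {ref!r}"
        )
    v = Variant.make(first, ref, alt or "")
    v.validate_against(query)
    return v


def format_variant(v: Variant) -> str:
    """Canonical string form; ``parse_variant(format_variant(v))`` round-trips."""
    if v.kind is VariantKind.SUBSTITUTION:
        return f"{v.ref}{v.position}{v.alt}"
    if v.kind is VariantKind.DELETION:
        if len(v.ref) == 1:
            return f"{v.ref}{v.position}del"
        last = v.position + len(v.ref) - 1
        return f"{v.ref[0]}{v.position}_{v.ref[-1]}{last}del"
    if v.kind is VariantKind.INSERTION:
        return f"{v.position}_{v.position + 1}ins{v.alt}"
    if len(v.ref) == 1:
        return f"{v.ref}{v.position}delins{v.alt}"
    last = v.position + len(v.ref) - 1
    return f"{v.ref[0]}{v.position}_{v.ref[-1]}{last}delins{v.alt}"


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def apply_variant(query: ProteinSequence, v: Variant) -> ProteinSequence:
    """Return the variant sequence Q' (ref replaced by alt at position)."""
    v.validate_against(query)
    if v.kind is VariantKind.INSERTION:
        cut = v.position  # insert after this many residues
        residues = query.residues[:cut] + v.alt + query.residues[cut:]
    else:
        start = v.position - 1
        residues = query.residues[:start] + v.alt + query.residues[start + len(v.ref):]
    if not residues:
        raise ValueError("variant deletes the entire sequence")
    return ProteinSequence(id=f"{query.id}|{format_variant(v)}", residues=residues)


def null_variant(query: ProteinSequence, position: int) -> Variant:
    """Identity substitution at ``position`` (used as a zero-delta control)."""
    r = query.residue(position)
    return Variant(VariantKind.SUBSTITUTION, position, r, r)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    seqs = [
        ProteinSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_variant_tsv(path: Union[str, Path], query: ProteinSequence) -> list[VariantRecord]:
    """Read a variant TSV: column 1 = variant string, optional column 2 = label.

    Lines starting with ``#`` are ignored.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                variant = parse_variant(parts[0], query)
            except ValueError as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from None
            label = VariantLabel.UNKNOWN
            if len(parts) > 1 and parts[1].strip():
                try:
                    label = VariantLabel(parts[1].strip().lower())
                except ValueError:
                    raise VariantSyntaxError(
                        f"{path}:{lineno}: unknown label {parts[1]!r}"
                    ) from None
            records.append(VariantRecord(variant, label))
    return records


def write_variant_tsv(records: Iterable[VariantRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec in records:
            row = [format_variant(rec.variant)]
            if rec.label is not VariantLabel.UNKNOWN:
                row.append(rec.label.value)
            writer.writerow(row)
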