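"""Score-only semi-global (free end-gap) pairwise alignment with affine gaps.

The aligner is the workhorse underneath every delta-score computation: it
returns the optimal *overlap* alignment score between two protein sequences,
where gaps hanging off either end of either sequence are free and internal
gaps are charged with affine costs under an NCBI-format substitution matrix
(BLOSUM62 bundled as the default).

Only scores are computed (three-state Gotoh recurrence, integer arithmetic);
no traceback is stored.  A companion entry point additionally reports the
number of identical aligned pairs on a best-scoring alignment, which drives
the identity clustering of homologs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np

__all__ = [
    "AlphabetError",
    "GapConvention",
    "GapPenalties",
    "SubstitutionMatrix",
    "semiglobal_score",
    "semiglobal_identity",
    "self_score",
]

# Sentinel for unreachable DP states; far from int64 limits so that
# subtracting gap costs can never wrap around.
_NEG = np.int64(-(2**40))

# Scale factor for the combined (score, identity) dynamic program.  A single
# int64 cell holds score * _K + identities; valid while identities < _K.
_K = 4096


class AlphabetError(ValueError):
    """A residue cannot be scored under the loaded substitution matrix."""


class GapConvention(enum.Enum):
    """How the opening penalty interacts with the first gap residue.

    ``FIRST_RESIDUE_COSTS_OPEN_ONLY`` (classic Gotoh): a length-L gap costs
    ``open + (L - 1) * extend``.  ``OPEN_PLUS_PER_RESIDUE``: a length-L gap
    costs ``open + L * extend``.
    """

    FIRST_RESIDUE_COSTS_OPEN_ONLY = "first_residue_costs_open_only"
    OPEN_PLUS_PER_RESIDUE = "open_plus_per_residue"


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap costs (both values are penalties, i.e. non-negative)."""

    open: int = 10
    extend: int = 1
    convention: GapConvention = GapConvention.FIRST_RESIDUE_COSTS_OPEN_ONLY

    def __post_init__(self) -> None:
        if not (self.open >= self.extend >= 0):
            raise ValueError(
                f"gap penalties must satisfy open >= extend >= 0, "
                f"got open={self.open}, extend={self.extend}"
            )

    @property
    def effective_open(self) -> int:
        """Cost charged for the first residue of an internal gap."""
        if self.convention is GapConvention.OPEN_PLUS_PER_RESIDUE:
            return self.open + self.extend
        return self.open

    def gap_cost(self, length: int) -> int:
        """Total cost of an internal gap of ``length`` residues."""
        if length <= 0:
            return 0
        return self.effective_open + (length - 1) * self.extend


class SubstitutionMatrix:
    """Integer-valued symmetric residue scoring matrix.

    Parsed from the standard NCBI plain-text format (``#`` comments, a header
    row of symbols, one labelled row per symbol).  Residues are scored through
    :meth:`encode`; the ``*`` column present in distributed files is kept in
    the table but is not an encodable residue.
    """

    #: residues that may appear in sequences (20 standard + ambiguity codes)
    SCORABLE = set("ARNDCQEGHILKMFPSTWYVBZX")

    def __init__(self, name: str, symbols: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=np.int64)
        if scores.shape != (len(symbols), len(symbols)):
            raise ValueError("matrix shape does not match symbol list")
        if not np.array_equal(scores, scores.T):
            raise ValueError(f"substitution matrix {name!r} is not symmetric")
        self.name = name
        self.symbols = symbols
        self.scores = scores
        self._index: dict[str, int] = {s: i for i, s in enumerate(symbols)}
        # combined matrix for the (score, identity) DP: score * _K + (a == b)
        eye = np.eye(len(symbols), dtype=np.int64)
        self._combined = scores * _K + eye

    # -- loading ---------------------------------------------------------

    @classmethod
    def from_file(cls, path: Union[str, Path], name: str | None = None) -> "SubstitutionMatrix":
        path = Path(path)
        return cls._parse(path.read_text().splitlines(), name or path.stem)

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Load a matrix bundled with the package (default BLOSUM62)."""
        ref = resources.files("provean").joinpath("matrices").joinpath(name)
        if not ref.is_file():
            raise FileNotFoundError(f"no bundled substitution matrix named {name!r}")
        return cls._parse(ref.read_text().splitlines(), name)

    @classmethod
    def _parse(cls, lines: Iterable[str], name: str) -> "SubstitutionMatrix":
        rows: list[list[int]] = []
        header: list[str] = []
        row_syms: list[str] = []
        for ln in lines:
            ln = ln.rstrip()
            if not ln or ln.lstrip().startswith("#"):
                continue
            parts = ln.split()
            if not header:
                header = parts
                continue
            row_syms.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
        if not header:
            raise ValueError(f"matrix {name!r}: no header row found")
        if row_syms != header:
            raise ValueError(f"matrix {name!r}: row labels do not match header")
        return cls(name, "".join(header), np.array(rows, dtype=np.int64))

    # -- lookups ---------------------------------------------------------

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        try:
            return int(self.scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise AlphabetError(f"residue {exc.args[0]!r} not in matrix {self.name!r}") from None

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to matrix row indices (uppercase expected)."""
        try:
            return np.fromiter(
                (self._index[_checked(c, self)] for c in residues),
                dtype=np.int64,
                count=len(residues),
            )
        except KeyError as exc:  # pragma: no cover - _checked raises first
            raise AlphabetError(f"residue {exc.args[0]!r} not scorable") from None

    def is_diagonal_dominant(self) -> bool:
        """True when every standard residue's self-score is the maximum of its
        row over standard residues (BLOSUM62 is; ambiguity codes are excluded
        because e.g. X–X scores below X–A)."""
        residues = [s for s in self.symbols if s in self.SCORABLE and s not in "BZX"]
        idx = [self._index[s] for s in residues]
        sub = self.scores[np.ix_(idx, idx)]
        return bool(np.all(sub.diagonal() == sub.max(axis=1)))


def _checked(c: str, m: SubstitutionMatrix) -> str:
    if c not in m.SCORABLE or c not in m._index:
        raise AlphabetError(
            f"residue {c!r} cannot be scored under matrix {m.name!r}"
        )
    return c


# ---------------------------------------------------------------------------
# Core dynamic program
# ---------------------------------------------------------------------------

def _residues(seq) -> str:
    res = getattr(seq, "residues", seq)
    if not isinstance(res, str):
        raise TypeError(f"expected sequence or residue string, got {type(seq)!r}")
    return res


def _dp_combined(ai: np.ndarray, bi: np.ndarray, table: np.ndarray, go: int, ge: int) -> int:
    """Best combined value over all semi-global alignments.

    ``table`` holds per-pair combined contributions; ``go``/``ge`` are combined
    gap costs.  Free end gaps are realised by zero-initialised first row/column
    and by maximising over the last row and last column.  The horizontal gap
    state is vectorised with a running-max transform: unrolling
    ``E[j] = max(H[j-1] - go, E[j-1] - ge)`` gives
    ``E[j] = max_{k<j}(H[k] + k*ge) - go - (j-1)*ge`` (valid while go >= ge).
    """
    m, n = len(ai), len(bi)
    H = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n + 1, _NEG, dtype=np.int64)
    jge = np.arange(n + 1, dtype=np.int64) * ge
    best_last_col = np.int64(0)  # H[i][n] over all i; row 0 contributes 0
    for i in range(m):
        F = np.maximum(H - go, F - ge)
        G = np.empty(n + 1, dtype=np.int64)
        G[0] = 0
        np.maximum(H[:-1] + table[ai[i], bi], F[1:], out=G[1:])
        run = np.maximum.accumulate(G + jge)
        H = G  # reuse buffer; G[j] already max(diagonal, vertical)
        E = run[:-1] - go - jge[1:] + ge
        np.maximum(G[1:], E, out=H[1:])
        H[0] = 0
        if H[n] > best_last_col:
            best_last_col = H[n]
    return int(max(int(H.max()), int(best_last_col)))


def _prepare(a, b, matrix: SubstitutionMatrix | None, gaps: GapPenalties | None):
    matrix = matrix if matrix is not None else SubstitutionMatrix.load()
    gaps = gaps if gaps is not None else GapPenalties()
    ra, rb = _residues(a), _residues(b)
    if not ra or not rb:
        raise ValueError("cannot align empty sequences")
    if max(len(ra), len(rb)) >= _K:
        raise ValueError(f"sequences longer than {_K - 1} residues are not supported")
    return matrix.encode(ra), matrix.encode(rb), matrix, gaps


def semiglobal_score(a, b, matrix: SubstitutionMatrix | None = None,
                     gaps: GapPenalties | None = None) -> int:
    """Optimal semi-global alignment score between ``a`` and ``b``.

    End gaps on either end of either sequence are free; internal gaps are
    charged affinely per ``gaps``.  Accepts residue strings or any object
    with a ``residues`` attribute.
    """
    ai, bi, matrix, gaps = _prepare(a, b, matrix, gaps)
    combined = _dp_combined(ai, bi, matrix._combined, gaps.effective_open * _K,
                            gaps.extend * _K)
    return combined // _K


def semiglobal_identity(a, b, matrix: SubstitutionMatrix | None = None,
                        gaps: GapPenalties | None = None) -> tuple[int, int]:
    """``(score, identities)`` for a best-scoring semi-global alignment.

    Among all alignments achieving the optimal score, the one with the most
    identical aligned residue pairs is reported (lexicographic DP on the
    combined value score * K + identities).
    """
    ai, bi, matrix, gaps = _prepare(a, b, matrix, gaps)
    combined = _dp_combined(ai, bi, matrix._combined, gaps.effective_open * _K,
                            gaps.extend * _K)
    return combined // _K, combined % _K


def self_score(a, matrix: SubstitutionMatrix | None = None,
               gaps: GapPenalties | None = None) -> int:
    """Semi-global score of a sequence against itself.

    For a diagonal-dominant matrix and positive gap costs this equals the sum
    of the diagonal scores of the sequence's residues.
    """
    return semiglobal_score(a, a, matrix, gaps)
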