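"""Independent brute-force oracles used by the test suite.

Nothing here may call into the package's alignment/score internals: the
enumeration aligner walks every monotone alignment path explicitly, and the
metric oracles count pairs/cut-points directly.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


def gap_cost(length: int, open_: int, extend: int, per_residue: bool = False) -> int:
    if length <= 0:
        return 0
    if per_residue:
        return open_ + length * extend
    return open_ + (length - 1) * extend


@lru_cache(maxsize=None)
def all_paths(m: int, n: int) -> tuple[str, ...]:
    """Every monotone alignment path from (0,0) to (m,n) as M/D/I strings.

    D consumes a residue of the first sequence, I of the second, M of both.
    """
    if m == 0 and n == 0:
        return ("",)
    out = []
    if m > 0 and n > 0:
        out.extend(p + "M" for p in all_paths(m - 1, n - 1))
    if m > 0:
        out.extend(p + "D" for p in all_paths(m - 1, n))
    if n > 0:
        out.extend(p + "I" for p in all_paths(m, n - 1))
    return tuple(out)


def path_score_and_identity(path: str, a: str, b: str, lookup, open_: int,
                            extend: int, per_residue: bool = False) -> tuple[int, int]:
    """Score one path; gap runs touching either end of the path are free."""
    score = 0
    ident = 0
    i = j = 0
    k = 0
    L = len(path)
    while k < L:
        move = path[k]
        if move == "M":
            score += lookup(a[i], b[j])
            ident += a[i] == b[j]
            i += 1
            j += 1
            k += 1
            continue
        run_start = k
        while k < L and path[k] == move:
            k += 1
        run_len = k - run_start
        if move == "D":
            i += run_len
        else:
            j += run_len
        if run_start != 0 and k != L:  # internal gap run
            score -= gap_cost(run_len, open_, extend, per_residue)
    return score, ident


def semiglobal_score_oracle(a: str, b: str, lookup, open_: int = 10,
                            extend: int = 1, per_residue: bool = False) -> int:
    """Max score over all alignments, free end gaps (enumeration)."""
    return max(
        path_score_and_identity(p, a, b, lookup, open_, extend, per_residue)[0]
        for p in all_paths(len(a), len(b))
    )


def semiglobal_identity_oracle(a: str, b: str, lookup, open_: int = 10,
                               extend: int = 1) -> tuple[int, int]:
    """(best score, max identities among best-scoring alignments)."""
    best = max(
        (path_score_and_identity(p, a, b, lookup, open_, extend)
         for p in all_paths(len(a), len(b))),
        key=lambda t: (t[0], t[1]),
    )
    return best


# ---------------------------------------------------------------------------
# Clustering oracle: independent restatement of the greedy rule
# ---------------------------------------------------------------------------

def greedy_cluster_oracle(seqs, identity_fn, threshold: float):
    """Partition ids by the greedy longest-first rule.

    ``seqs`` is a list of (id, residues); ``identity_fn(res_a, res_b)``
    returns the identity fraction.  Returns a list of lists of ids, clusters
    in founding order, members in joining order.
    """
    ordered = sorted(seqs, key=lambda s: (-len(s[1]), s[1], s[0]))
    reps: list[tuple[str, str]] = []
    clusters: list[list[str]] = []
    for sid, res in ordered:
        for ci, (rid, rres) in enumerate(reps):
            if identity_fn(res, rres) >= threshold:
                clusters[ci].append(sid)
                break
        else:
            reps.append((sid, res))
            clusters.append([sid])
    return clusters


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------

def sens_spec_at(dele, neut, threshold):
    sens = sum(1 for s in dele if s <= threshold) / len(dele) * 100.0
    spec = sum(1 for s in neut if s > threshold) / len(neut) * 100.0
    return sens, spec


def best_min_sens_spec(dele, neut) -> float:
    """Brute-force max over all cut points of min(sensitivity, specificity)."""
    candidates = sorted(set(dele) | set(neut))
    # every interval between adjacent distinct scores, plus the extremes
    cuts = [candidates[0] - 1.0]
    cuts += [(x + y) / 2.0 for x, y in zip(candidates, candidates[1:])]
    cuts += [candidates[-1] + 1.0]
    cuts += candidates  # thresholds exactly at observed scores
    return max(min(sens_spec_at(dele, neut, t)) for t in cuts)


def auc_all_pairs(dele, neut) -> float:
    """(wins + half ties) / (n_d * n_n), deleterious wins when scored lower."""
    wins = 0.0
    for d in dele:
        for n in neut:
            if d < n:
                wins += 1.0
            elif d == n:
                wins += 0.5
    return wins / (len(dele) * len(neut))
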