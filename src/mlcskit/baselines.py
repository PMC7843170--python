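"""Pairwise dynamic-programming baselines and the brute-force MLCS oracle.

The pairwise routines are user-facing algorithms for n = 2 (full-matrix and
two-row length computation, exhaustive LCS enumeration).  The n-dimensional
oracle fills the complete position lattice with no pruning whatsoever, so it
shares no machinery — and hence no bugs — with the dominant-point engine; it
is the ground truth the engine is tested against.
"""

from __future__ import annotations

import itertools
from typing import Union

import numpy as np

from .errors import BudgetExceededError, ParameterError
from .sequences_io import BioSequence, ResultReport, SequenceSet

DEFAULT_LATTICE_BUDGET = 10**6
DEFAULT_ENUM_BUDGET = 10**6

SeqLike = Union[str, BioSequence]


def _residues(s: SeqLike) -> str:
    return s.residues if isinstance(s, BioSequence) else s


def dp_matrix(s1: SeqLike, s2: SeqLike) -> np.ndarray:
    """Full (len1+1) x (len2+1) LCS-length matrix; L[i, j] scores the prefixes."""
    a, b = _residues(s1), _residues(s2)
    L = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int64)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                L[i, j] = L[i - 1, j - 1] + 1
            else:
                L[i, j] = max(L[i - 1, j], L[i, j - 1])
    return L


def dp_lcs_length(s1: SeqLike, s2: SeqLike) -> int:
    """LCS length of a pair by the standard full-matrix dynamic program."""
    return int(dp_matrix(s1, s2)[-1, -1])


def space_opt_lcs_length(s1: SeqLike, s2: SeqLike) -> int:
    """LCS length keeping only two matrix rows (linear-space length computation)."""
    a, b = _residues(s1), _residues(s2)
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    curr = np.zeros(len(b) + 1, dtype=np.int64)
    for i in range(1, len(a) + 1):
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                curr[j] = prev[j - 1] + 1
            else:
                curr[j] = max(prev[j], curr[j - 1])
        prev, curr = curr, prev
    return int(prev[-1])


def dp_enumerate_all_lcs(
    s1: SeqLike, s2: SeqLike, budget: int = DEFAULT_ENUM_BUDGET
) -> set[str]:
    """All distinct LCS strings of a pair via memoized backtracking over the
    full matrix.  ``budget`` caps the total number of stored strings."""
    a, b = _residues(s1), _residues(s2)
    L = dp_matrix(s1, s2)
    memo: dict[tuple[int, int], frozenset[str]] = {}
    stored = 0

    def rec(i: int, j: int) -> frozenset[str]:
        nonlocal stored
        if L[i, j] == 0:
            return frozenset([""])
        key = (i, j)
        if key in memo:
            return memo[key]
        out: set[str] = set()
        if i > 0 and j > 0 and a[i - 1] == b[j - 1] and L[i, j] == L[i - 1, j - 1] + 1:
            out |= {s + a[i - 1] for s in rec(i - 1, j - 1)}
        if i > 0 and L[i - 1, j] == L[i, j]:
            out |= rec(i - 1, j)
        if j > 0 and L[i, j - 1] == L[i, j]:
            out |= rec(i, j - 1)
        stored += len(out)
        if stored > budget:
            raise BudgetExceededError(f"LCS enumeration budget {budget} exceeded")
        memo[key] = frozenset(out)
        return memo[key]

    return set(rec(len(a), len(b)))


def brute_force_mlcs(
    seqs: SequenceSet,
    lattice_budget: int = DEFAULT_LATTICE_BUDGET,
    enum_budget: int = DEFAULT_ENUM_BUDGET,
) -> ResultReport:
    """Exact MLCS of n >= 2 sequences by the unpruned n-dimensional dynamic
    program over the full position lattice, then exhaustive backtracking.

    Exponential in n by design — this is the ground-truth oracle, usable only
    when the product of (length_i + 1) fits ``lattice_budget``.  The report's
    ``path_count`` equals the distinct-string count (there is no DAG here).
    """
    strings = seqs.residue_strings()
    n = len(strings)
    shape = tuple(len(s) + 1 for s in strings)
    cells = 1
    for d in shape:
        cells *= d
    if cells > lattice_budget:
        raise BudgetExceededError(
            f"lattice of {cells} cells exceeds the budget of {lattice_budget}"
        )
    L = np.zeros(shape, dtype=np.int64)
    for idx in np.ndindex(shape):
        if 0 in idx:
            continue
        if all(strings[i][idx[i] - 1] == strings[0][idx[0] - 1] for i in range(1, n)):
            diag = tuple(x - 1 for x in idx)
            best = L[diag] + 1
        else:
            best = 0
        for i in range(n):
            if idx[i] > 0:
                prev = idx[:i] + (idx[i] - 1,) + idx[i + 1 :]
                v = L[prev]
                if v > best:
                    best = v
        L[idx] = best

    memo: dict[tuple[int, ...], frozenset[str]] = {}
    stored = 0

    def rec(idx: tuple[int, ...]) -> frozenset[str]:
        nonlocal stored
        if L[idx] == 0:
            return frozenset([""])
        if idx in memo:
            return memo[idx]
        out: set[str] = set()
        if all(x > 0 for x in idx) and all(
            strings[i][idx[i] - 1] == strings[0][idx[0] - 1] for i in range(1, n)
        ):
            diag = tuple(x - 1 for x in idx)
            if L[idx] == L[diag] + 1:
                c = strings[0][idx[0] - 1]
                out |= {s + c for s in rec(diag)}
        for i in range(n):
            if idx[i] > 0:
                prev = idx[:i] + (idx[i] - 1,) + idx[i + 1 :]
                if L[prev] == L[idx]:
                    out |= rec(prev)
        stored += len(out)
        if stored > enum_budget:
            raise BudgetExceededError(f"MLCS enumeration budget {enum_budget} exceeded")
        memo[idx] = frozenset(out)
        return memo[idx]

    end = tuple(len(s) for s in strings)
    length = int(L[end])
    found = sorted(rec(end)) if length > 0 else []
    return ResultReport(tuple(found), length, len(found), len(found))
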