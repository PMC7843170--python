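"""Level-wise dominant-point search: the core of exact MLCS computation.

A match point is an n-vector of 1-based positions at which all n sequences
carry the same symbol; its level k is the length of the common subsequence
spelled along its parent chain.  The search expands level k into level k+1
through the successor tables, then prunes the candidate set:

* duplicates (identical coordinate vectors) collapse into one point whose
  parent set is the union of the duplicates' parents;
* points strongly dominated by another candidate (strictly larger in every
  coordinate) are discarded — such a point provably lies on no longest
  path, so this pruning is lossless for exhaustive enumeration.

A weak-dominance variant (discard when another candidate is <= in every
coordinate) is also provided.  It yields the same maximal length L and the
classic, smaller "k-dominant" level sets, but it can drop co-optimal
spellings that share a coordinate with a retained point, so it must not be
used when *all* distinct MLCS strings are wanted; see docs/methods.md for a
two-sequence counterexample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, TextIO

import numpy as np

from .errors import BudgetExceededError, ConfigError, ParameterError
from .sequences_io import SequenceSet
from .successor_table import (
    NO_SUCCESSOR,
    SuccessorTable,
    SuffixCountTable,
    build_successor_tables,
    build_suffix_counts,
    successor_match_points,
)

DEFAULT_NODE_BUDGET = 10**6


@dataclass(eq=False)
class MatchPoint:
    """A retained lattice point: positions, level, matched symbol, parent links.

    ``symbol`` is None only for the virtual source (the all-zero vector at
    level 0).  Identity semantics (``eq=False``) — parent sets hold object
    references, and distinct objects may never share a coordinate vector
    within one level after pruning.
    """

    positions: tuple[int, ...]
    level: int
    symbol: Optional[str] = None
    parents: set["MatchPoint"] = field(default_factory=set)

    @property
    def n(self) -> int:
        return len(self.positions)

    def __repr__(self) -> str:  # compact, for debugging and DOT labels
        return f"MatchPoint({list(self.positions)}@{self.level}:{self.symbol or 'src'})"


@dataclass
class LevelSet:
    """All points retained at one level, kept in lexicographic position order."""

    k: int
    points: list[MatchPoint]


@dataclass(frozen=True)
class PruneOptions:
    """Pruning configuration.

    mode "pf" applies dominance pruning only; "hf" additionally discards
    candidates whose admissible upper bound proves they cannot reach the
    greedy lower bound (computed at search start), which never changes the
    result.  ``dominance`` selects the pruning predicate; "strong" is the
    enumeration-safe default.
    """

    mode: str = "pf"
    dominance: str = "strong"
    lower_bound: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("pf", "hf"):
            raise ConfigError(f"unknown prune mode {self.mode!r} (expected pf or hf)")
        if self.dominance not in ("strong", "weak"):
            raise ConfigError(f"unknown dominance {self.dominance!r} (expected strong or weak)")
        if self.lower_bound < 0:
            raise ConfigError("lower_bound must be >= 0")


def dominates(p: tuple[int, ...], q: tuple[int, ...]) -> tuple[bool, bool]:
    """Return ``(weak, strict)``: p <= q in every coordinate / p < q in every coordinate."""
    if len(p) != len(q):
        raise ParameterError(f"dimension mismatch: {len(p)} vs {len(q)}")
    weak = all(a <= b for a, b in zip(p, q))
    strict = all(a < b for a, b in zip(p, q))
    return weak, strict


def _merge_duplicates(candidates: Iterable[MatchPoint]) -> list[MatchPoint]:
    """Collapse identical coordinate vectors, unioning parent sets; lex order."""
    merged: dict[tuple[int, ...], MatchPoint] = {}
    for mp in candidates:
        rep = merged.get(mp.positions)
        if rep is None:
            merged[mp.positions] = mp
        else:
            rep.parents |= mp.parents
    return [merged[key] for key in sorted(merged)]


def prune_minima(candidates: Iterable[MatchPoint], dominance: str = "strong") -> list[MatchPoint]:
    """Remove dominated candidates from one level.

    With ``dominance="strong"`` a candidate is dropped iff another candidate
    is strictly smaller in every coordinate (lossless for enumeration).
    With ``dominance="weak"`` it is dropped iff another *distinct* candidate
    is <= in every coordinate — the classic k-dominant filter.  Duplicates
    always collapse to one representative with merged parents.  All
    candidates must share one level.
    """
    cands = list(candidates)
    if not cands:
        return []
    levels = {mp.level for mp in cands}
    if len(levels) != 1:
        raise ParameterError(f"prune_minima requires a single level, got levels {sorted(levels)}")
    cands = _merge_duplicates(cands)
    m = len(cands)
    if m == 1:
        return cands
    pos = np.array([mp.positions for mp in cands], dtype=np.int64)  # (m, n)
    if dominance == "strong":
        lt_all = (pos[:, None, :] < pos[None, :, :]).all(axis=2)  # lt_all[j,i]: j < i everywhere
        dominated = lt_all.any(axis=0)
    elif dominance == "weak":
        le_all = (pos[:, None, :] <= pos[None, :, :]).all(axis=2)
        np.fill_diagonal(le_all, False)  # vectors are distinct after the merge
        dominated = le_all.any(axis=0)
    else:
        raise ConfigError(f"unknown dominance {dominance!r}")
    return [mp for mp, dead in zip(cands, dominated) if not dead]


def upper_bound(point: "MatchPoint | tuple[int, ...]", counts: SuffixCountTable) -> int:
    """Admissible bound on the length of any common subsequence extending ``point``.

    Sum over symbols of the minimum, across sequences, of the symbol's
    remaining occurrences — each symbol can contribute at most that many
    further matches, so the bound never underestimates.
    """
    pos = point.positions if isinstance(point, MatchPoint) else tuple(point)
    total = 0
    for ci in range(len(counts.alphabet)):
        total += min(int(arr[ci, p]) for arr, p in zip(counts.counts, pos))
    return total


def expand_level(
    current: LevelSet,
    tables: list[SuccessorTable],
    opts: PruneOptions,
    counts: Optional[SuffixCountTable] = None,
    stats: Optional[list[tuple[int, int, int]]] = None,
) -> LevelSet:
    """Generate level k+1 from level k: successors, optional bound filter, pruning."""
    if opts.mode == "hf" and counts is None:
        raise ConfigError("hf prune mode requires a SuffixCountTable")
    k = current.k
    if not current.points:
        if stats is not None:
            stats.append((k + 1, 0, 0))
        return LevelSet(k + 1, [])
    n = len(tables)
    sigma = len(tables[0].alphabet)
    symbols = tables[0].alphabet.symbols
    pos = np.array([mp.positions for mp in current.points], dtype=np.int64)  # (m, n)
    candidates: dict[tuple[int, ...], MatchPoint] = {}
    n_candidates = 0
    for ci in range(sigma):
        nxt = np.stack(
            [tables[i].table[ci, pos[:, i]] for i in range(n)], axis=1
        )  # (m, n) successor vectors for this symbol
        ok = (nxt != NO_SUCCESSOR).all(axis=1)
        for row in np.flatnonzero(ok):
            vec = tuple(int(v) for v in nxt[row])
            parent = current.points[row]
            n_candidates += 1
            mp = candidates.get(vec)
            if mp is None:
                candidates[vec] = MatchPoint(vec, k + 1, symbols[ci], {parent})
            else:
                mp.parents.add(parent)
    cands = list(candidates.values())
    if opts.mode == "hf":
        cands = [
            mp for mp in cands if (k + 1) + upper_bound(mp, counts) >= opts.lower_bound
        ]
    retained = prune_minima(cands, opts.dominance)
    if stats is not None:
        stats.append((k + 1, n_candidates, len(retained)))
    return LevelSet(k + 1, retained)


def greedy_lower_bound(tables: list[SuccessorTable]) -> int:
    """Length of a greedy common subsequence: from the source, repeatedly take
    the symbol whose successor vector has the smallest coordinate sum (ties
    broken by alphabet order)."""
    point = tuple(0 for _ in tables)
    length = 0
    while True:
        cands = successor_match_points(point, tables)
        if not cands:
            return length
        # dict preserves alphabet order, so min() on the sum alone is tie-stable
        point = min(cands.values(), key=sum)
        length += 1


def run_dominant_point_search(
    seqs: SequenceSet,
    opts: Optional[PruneOptions] = None,
    node_budget: int = DEFAULT_NODE_BUDGET,
    stats_file: Optional[TextIO] = None,
):
    """Full breadth-first dominant-point search over a sequence set.

    Expands level sets from the virtual all-zero source until a level comes
    back empty; the last non-empty level is the MLCS length L.  Returns the
    trimmed DAG of retained points (see :mod:`mlcskit.mlcs_graph`).  A node
    budget guards against exponential blow-up on adversarial inputs.
    """
    from .mlcs_graph import build_graph  # local import to avoid a cycle

    if seqs.n < 2:
        raise ParameterError(f"need at least 2 sequences, got {seqs.n}")
    opts = opts or PruneOptions()
    tables = build_successor_tables(seqs)
    counts = build_suffix_counts(seqs) if opts.mode == "hf" else None
    if opts.mode == "hf" and opts.lower_bound == 0:
        opts = replace(opts, lower_bound=greedy_lower_bound(tables))
    stats: Optional[list[tuple[int, int, int]]] = [] if stats_file is not None else None

    source = MatchPoint(tuple(0 for _ in range(seqs.n)), 0, None)
    levels = [LevelSet(0, [source])]
    retained_total = 1
    while levels[-1].points:
        nxt = expand_level(levels[-1], tables, opts, counts, stats)
        retained_total += len(nxt.points)
        if retained_total > node_budget:
            raise BudgetExceededError(
                f"node budget {node_budget} exceeded at level {nxt.k} "
                f"({retained_total} points retained)"
            )
        levels.append(nxt)
    if stats_file is not None and stats is not None:
        stats_file.write("level\tcandidates\tretained\n")
        for k, nc, nr in stats:
            stats_file.write(f"{k}\t{nc}\t{nr}\n")
    return build_graph(levels[:-1])  # drop the trailing empty level
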