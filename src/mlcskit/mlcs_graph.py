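"""The dominant-point DAG and exhaustive MLCS enumeration.

Every retained point that lies on a path from the virtual source to a
maximum-level point becomes a node; parent links recorded during expansion
become edges.  Each edge raises the level by exactly one, so every
source-to-sink path has exactly L edges and spells one length-L common
subsequence; depth-first traversal enumerates them all.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .errors import BudgetExceededError, GraphIntegrityError, ParameterError
from .dominant_points import LevelSet, MatchPoint
from .sequences_io import ResultReport, SequenceSet

DEFAULT_ENUM_BUDGET = 10**6


@dataclass
class MLCSGraph:
    """A leveled DAG: level 0 holds only the virtual source, level L the sinks."""

    source: MatchPoint
    levels: list[list[MatchPoint]]  # levels[k] sorted by (symbol, positions)
    children: dict[MatchPoint, list[MatchPoint]]

    @property
    def L(self) -> int:
        return len(self.levels) - 1

    @property
    def sinks(self) -> list[MatchPoint]:
        return self.levels[-1] if self.L > 0 else []

    @property
    def node_count(self) -> int:
        return sum(len(lv) for lv in self.levels)

    def to_dot(self) -> str:
        """DOT-format text export; node label = positions:level."""
        lines = ["digraph mlcs {", "  rankdir=LR;"]
        name = {mp: f"n{idx}" for idx, mp in enumerate(p for lv in self.levels for p in lv)}
        for lv in self.levels:
            for mp in lv:
                label = ",".join(str(p) for p in mp.positions) + f":{mp.level}"
                if mp.symbol:
                    label += f" {mp.symbol}"
                lines.append(f'  {name[mp]} [label="{label}"];')
        for parent, kids in self.children.items():
            for kid in kids:
                lines.append(f"  {name[parent]} -> {name[kid]};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def _sort_key(mp: MatchPoint) -> tuple:
    return (mp.symbol or "", mp.positions)


def build_graph(levelsets: list[LevelSet]) -> MLCSGraph:
    """Trim retained level sets to the nodes on maximal paths and wire edges.

    A point retained at level k can be a dead end (no surviving children);
    such points lie on no source-to-sink longest path and are removed by a
    backward sweep from the last level.  Parents of kept nodes were
    themselves retained at the previous level, so the sweep is closed.
    """
    if not levelsets or levelsets[0].k != 0 or len(levelsets[0].points) != 1:
        raise GraphIntegrityError("level 0 must hold exactly the virtual source")
    source = levelsets[0].points[0]
    L = len(levelsets) - 1
    if L == 0:
        return MLCSGraph(source, [[source]], {})
    kept: list[list[MatchPoint]] = [[] for _ in range(L + 1)]
    kept[L] = sorted(levelsets[L].points, key=_sort_key)
    keep_set = set(kept[L])
    for k in range(L - 1, -1, -1):
        layer = {p for mp in kept[k + 1] for p in mp.parents}
        kept[k] = sorted(layer, key=_sort_key)
        keep_set |= layer
    children: dict[MatchPoint, list[MatchPoint]] = {}
    for k in range(1, L + 1):
        for mp in kept[k]:
            for parent in mp.parents:
                children.setdefault(parent, []).append(mp)
    for kids in children.values():
        kids.sort(key=_sort_key)
    return MLCSGraph(source, kept, children)


def _verify_graph(graph: MLCSGraph) -> None:
    L = graph.L
    if graph.levels[0] != [graph.source] or graph.source.level != 0:
        raise GraphIntegrityError("level 0 must hold exactly the virtual source")
    seen = set(graph.levels[0])
    for k in range(1, L + 1):
        if not graph.levels[k]:
            raise GraphIntegrityError(f"level gap: level {k} of {L} is empty")
        for mp in graph.levels[k]:
            if mp.level != k:
                raise GraphIntegrityError(f"node {mp!r} stored at level {k}")
            live_parents = [p for p in mp.parents if p in seen]
            if not live_parents:
                raise GraphIntegrityError(f"node {mp!r} unreachable from the source")
        seen |= set(graph.levels[k])
    for parent, kids in graph.children.items():
        for kid in kids:
            if kid.level != parent.level + 1:
                raise GraphIntegrityError(
                    f"edge {parent!r} -> {kid!r} does not raise the level by 1"
                )
    for k in range(L):  # every non-sink node must lead somewhere
        for mp in graph.levels[k]:
            if not graph.children.get(mp):
                raise GraphIntegrityError(f"dead-end node {mp!r} at level {k} of {L}")


def backtrack_enumerate(
    graph: MLCSGraph,
    enum_budget: int = DEFAULT_ENUM_BUDGET,
    child_order_seed: Optional[int] = None,
) -> ResultReport:
    """Depth-first enumeration of every source-to-sink path, spelling one
    common subsequence per path.

    Children are visited in (symbol, positions) order for reproducibility;
    ``child_order_seed`` shuffles that order (a hook for verifying that the
    deduplicated string set is traversal-order invariant).  Distinct strings
    are reported sorted; ``path_count`` counts raw paths.
    """
    _verify_graph(graph)
    L = graph.L
    if L == 0:
        return ResultReport((), 0, 0, 0)
    rng = random.Random(child_order_seed) if child_order_seed is not None else None
    strings: set[str] = set()
    path_count = 0
    # iterative DFS; stack frames: (node, spelled prefix)
    stack: list[tuple[MatchPoint, str]] = [(graph.source, "")]
    while stack:
        node, prefix = stack.pop()
        if node.level == L:
            path_count += 1
            if path_count > enum_budget:
                raise BudgetExceededError(
                    f"enumeration budget {enum_budget} exceeded while backtracking"
                )
            strings.add(prefix)
            continue
        kids = graph.children[node]
        if rng is not None:
            kids = list(kids)
            rng.shuffle(kids)
        for kid in reversed(kids):  # reversed so the stack pops in sorted order
            stack.append((kid, prefix + kid.symbol))
    result = tuple(sorted(strings))
    return ResultReport(result, L, len(result), path_count)


def count_paths(graph: MLCSGraph) -> int:
    """Source-to-sink path count by per-node memoized summation.

    An independent second method: dynamic programming over levels from the
    sinks backwards, no traversal involved.  Must agree with the DFS
    ``path_count``.
    """
    _verify_graph(graph)
    if graph.L == 0:
        return 0
    memo: dict[MatchPoint, int] = {mp: 1 for mp in graph.levels[-1]}
    for k in range(graph.L - 1, -1, -1):
        for mp in graph.levels[k]:
            memo[mp] = sum(memo[kid] for kid in graph.children[mp])
    return memo[graph.source]


@dataclass(frozen=True)
class VerificationResult:
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def is_subsequence(sub: str, full: str) -> bool:
    """Two-pointer subsequence scan."""
    it = iter(full)
    return all(ch in it for ch in sub)


def verify_result(report: ResultReport, seqs: SequenceSet) -> VerificationResult:
    """Independent check that every reported string really is a common
    subsequence of every input sequence and has the reported length."""
    violations: list[str] = []
    for s in report.mlcs_strings:
        if len(s) != report.length_L:
            violations.append(f"{s!r}: length {len(s)} != reported L {report.length_L}")
        for seq in seqs.sequences:
            if not is_subsequence(s, seq.residues):
                violations.append(f"{s!r}: not a subsequence of {seq.id!r}")
    return VerificationResult(tuple(violations))
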