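"""Successor tables: the preprocessing index behind fast match-point generation.

For a sequence of length m over an alphabet of size sigma, the successor
table answers "what is the first position strictly after position j carrying
symbol c?" in O(1), for every j in 0..m and every c.  Generating the match
points reachable from an n-dimensional position vector then costs one table
lookup per sequence per symbol instead of a scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError, ParameterError
from .sequences_io import Alphabet, BioSequence, SequenceSet

#: Sentinel for "no further occurrence".  Kept distinct from 0 because 0 is
#: the virtual pre-sequence coordinate, never a residue position.
NO_SUCCESSOR = -1


@dataclass(frozen=True)
class SuccessorTable:
    """Dense (symbol x position) next-occurrence index for one sequence.

    ``table[ci, j]`` is the smallest 1-based position > j whose residue is
    ``alphabet.symbols[ci]``, or :data:`NO_SUCCESSOR`.  Immutable after
    construction.
    """

    sequence_id: str
    alphabet: Alphabet
    length: int
    table: np.ndarray  # shape (len(alphabet), length + 1), dtype int

    def next_occ(self, symbol: str, position: int) -> Optional[int]:
        """Next 1-based position > ``position`` carrying ``symbol``, or None."""
        if not 0 <= position <= self.length:
            raise ParameterError(
                f"position {position} out of range 0..{self.length} for {self.sequence_id!r}"
            )
        v = int(self.table[self.alphabet.index(symbol), position])
        return None if v == NO_SUCCESSOR else v

    def to_tsv(self) -> str:
        """Debug dump: one row per symbol, columns are positions 0..length."""
        header = "symbol\t" + "\t".join(str(j) for j in range(self.length + 1))
        rows = [
            sym + "\t" + "\t".join(str(int(v)) for v in self.table[ci])
            for ci, sym in enumerate(self.alphabet.symbols)
        ]
        return "\n".join([header] + rows) + "\n"


def build_successor_table(seq: BioSequence, alphabet: Alphabet) -> SuccessorTable:
    """Build the next-occurrence table in one backward sweep, O(sigma * length)."""
    m = seq.length
    table = np.full((len(alphabet), m + 1), NO_SUCCESSOR, dtype=np.int64)
    index = {sym: ci for ci, sym in enumerate(alphabet.symbols)}
    for j in range(m - 1, -1, -1):
        table[:, j] = table[:, j + 1]
        sym = seq.residues[j]
        if sym not in index:
            raise InputError(
                f"sequence {seq.id!r} position {j + 1}: symbol {sym!r} "
                f"not in alphabet {alphabet.name!r}"
            )
        table[index[sym], j] = j + 1  # residue j (0-based) lives at position j+1
    return SuccessorTable(seq.id, alphabet, m, table)


def build_successor_tables(seqs: SequenceSet) -> list[SuccessorTable]:
    return [build_successor_table(s, seqs.alphabet) for s in seqs.sequences]


@dataclass(frozen=True)
class SuffixCountTable:
    """Per-sequence symbol counts in the suffix strictly after each position.

    ``counts[i][ci, j]`` = occurrences of symbol ``ci`` in sequence i at
    positions > j.  Feeds the admissible upper bound of the hf pruning mode.
    """

    alphabet: Alphabet
    counts: tuple[np.ndarray, ...]  # each shape (sigma, length_i + 1)

    def count(self, seq_index: int, symbol: str, position: int) -> int:
        arr = self.counts[seq_index]
        if not 0 <= position <= arr.shape[1] - 1:
            raise ParameterError(f"position {position} out of range for sequence {seq_index}")
        return int(arr[self.alphabet.index(symbol), position])


def build_suffix_counts(seqs: SequenceSet) -> SuffixCountTable:
    """Backward recurrence: count(c, j) = count(c, j+1) + [residue at j+1 == c]."""
    alphabet = seqs.alphabet
    index = {sym: ci for ci, sym in enumerate(alphabet.symbols)}
    arrays = []
    for seq in seqs.sequences:
        m = seq.length
        arr = np.zeros((len(alphabet), m + 1), dtype=np.int64)
        for j in range(m - 1, -1, -1):
            arr[:, j] = arr[:, j + 1]
            sym = seq.residues[j]
            if sym not in index:
                raise InputError(
                    f"sequence {seq.id!r} position {j + 1}: symbol {sym!r} "
                    f"not in alphabet {alphabet.name!r}"
                )
            arr[index[sym], j] += 1
        arrays.append(arr)
    return SuffixCountTable(alphabet, tuple(arrays))


def successor_match_points(
    point: tuple[int, ...], tables: list[SuccessorTable]
) -> dict[str, tuple[int, ...]]:
    """All match points directly reachable from an n-dimensional position vector.

    For each alphabet symbol c the candidate successor is the vector of
    per-sequence next occurrences of c after the given coordinates; c is in
    the result iff every coordinate is defined.  Every returned vector is a
    match point (all sequences carry c there) and is strictly greater than
    ``point`` in every coordinate.
    """
    if len(point) != len(tables):
        raise ParameterError(
            f"point has {len(point)} coordinates but there are {len(tables)} sequences"
        )
    for p, tab in zip(point, tables):
        if not 0 <= p <= tab.length:
            raise ParameterError(
                f"coordinate {p} out of range 0..{tab.length} for {tab.sequence_id!r}"
            )
    alphabet = tables[0].alphabet
    out: dict[str, tuple[int, ...]] = {}
    for ci, sym in enumerate(alphabet.symbols):
        vec = tuple(int(tab.table[ci, p]) for tab, p in zip(tables, point))
        if all(v != NO_SUCCESSOR for v in vec):
            out[sym] = vec
    return out
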