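"""Sequence sets: FASTA input, validation, synthesis, and result reports.

Positions are 1-based throughout the package; position 0 is the virtual
"before the first residue" coordinate used by the dominant-point engine.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from .errors import InputError, ParameterError

DNA_SYMBOLS = "ACGT"
#: The 20 standard amino acids, one-letter codes, alphabetical.
PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of allowed uppercase residue symbols.

    The two canonical alphabets are :meth:`dna` (4 nucleotides) and
    :meth:`protein` (20 standard amino acids).  Ambiguity codes (N, R, B, ...)
    are deliberately not included: dominant-point matching assumes exact
    symbol equality, so ambiguous residues must be either rejected or added
    explicitly with :meth:`extended`.
    """

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ParameterError(f"alphabet {self.name!r} has duplicate symbols")
        for s in self.symbols:
            if len(s) != 1 or not s.isupper():
                raise ParameterError(
                    f"alphabet {self.name!r}: symbol {s!r} is not a single uppercase character"
                )

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls("dna", tuple(DNA_SYMBOLS))

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls("protein", tuple(PROTEIN_SYMBOLS))

    @classmethod
    def from_name(cls, name: str) -> "Alphabet":
        try:
            return {"dna": cls.dna, "protein": cls.protein}[name]()
        except KeyError:
            raise ParameterError(f"unknown alphabet name {name!r} (expected dna or protein)")

    def extended(self, extra: str) -> "Alphabet":
        """Return a copy with additional (uppercased) symbols appended."""
        extra_syms = tuple(s for s in extra.upper() if s not in self.symbols)
        if not extra_syms:
            return self
        return Alphabet(f"{self.name}+{''.join(extra_syms)}", self.symbols + extra_syms)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise ParameterError(f"symbol {symbol!r} not in alphabet {self.name!r}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class BioSequence:
    """A named residue string.  ``residues[i - 1]`` is the residue at 1-based position i."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ParameterError(
                f"position {position} out of range 1..{self.length} for sequence {self.id!r}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class SequenceSet:
    """n >= 2 sequences sharing one alphabet — the unit of input to every algorithm."""

    alphabet: Alphabet
    sequences: tuple[BioSequence, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ParameterError(
                f"a sequence set needs at least 2 sequences, got {len(self.sequences)}"
            )

    @property
    def n(self) -> int:
        return len(self.sequences)

    def residue_strings(self) -> tuple[str, ...]:
        return tuple(s.residues for s in self.sequences)


@dataclass(frozen=True)
class ResultReport:
    """All distinct MLCS strings, their common length, and path statistics.

    ``count`` is the number of distinct strings (the headline "number of
    MLCS"); ``path_count`` counts distinct source-to-sink longest paths in
    the DAG, which may exceed ``count`` when several paths spell the same
    string.
    """

    mlcs_strings: tuple[str, ...]
    length_L: int
    count: int
    path_count: int

    def __post_init__(self) -> None:
        if list(self.mlcs_strings) != sorted(set(self.mlcs_strings)):
            raise ParameterError("mlcs_strings must be sorted and distinct")
        if any(len(s) != self.length_L for s in self.mlcs_strings):
            raise ParameterError("every MLCS string must have length length_L")
        if self.count != len(self.mlcs_strings):
            raise ParameterError("count must equal the number of distinct strings")
        if self.path_count < self.count:
            raise ParameterError("path_count cannot be smaller than the distinct-string count")


@dataclass(frozen=True)
class Violation:
    sequence_id: str
    position: int  # 1-based; 0 flags a whole-sequence problem (e.g. empty)
    symbol: str


@dataclass(frozen=True)
class ValidationResult:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


PathLike = Union[str, Path]


def _detect_alphabet(records: Iterable[str]) -> Alphabet:
    dna = set(DNA_SYMBOLS)
    if all(set(r) <= dna for r in records):
        return Alphabet.dna()
    return Alphabet.protein()


def parse_fasta(path: PathLike, alphabet: Union[Alphabet, str] = "auto") -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Residues are uppercased; record order is preserved.  With
    ``alphabet="auto"`` the set is tagged dna iff every residue is one of
    A, C, G, T, and protein otherwise.  Parsing does not validate residues —
    run :func:`validate_sequences` for that.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise InputError(f"input file is empty: {path}")
    # Pre-scan for diagnostics Bio.SeqIO does not provide (line numbers).
    header_line = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            header_line = lineno
        elif header_line is None:
            raise InputError(f"malformed FASTA: sequence data before any '>' header at line {lineno}")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) < 2:
        raise ParameterError(
            f"need at least 2 FASTA records, got {len(records)} in {path}"
        )
    for rec in records:
        if len(rec.seq) == 0:
            raise InputError(f"malformed FASTA: record {rec.id!r} has no residues")
    seqs = tuple(BioSequence(rec.id, str(rec.seq).upper()) for rec in records)
    if alphabet == "auto":
        alpha = _detect_alphabet(s.residues for s in seqs)
    elif isinstance(alphabet, str):
        alpha = Alphabet.from_name(alphabet)
    else:
        alpha = alphabet
    return SequenceSet(alpha, seqs)


def validate_sequences(seqs: SequenceSet) -> ValidationResult:
    """Check every residue against the declared alphabet.

    Violations are returned as data, not raised: each carries the sequence
    id, the 1-based position and the offending symbol.  An empty sequence is
    reported with position 0.
    """
    violations: list[Violation] = []
    allowed = set(seqs.alphabet.symbols)
    for seq in seqs.sequences:
        if seq.length == 0:
            violations.append(Violation(seq.id, 0, ""))
            continue
        for pos, sym in enumerate(seq.residues, start=1):
            if sym not in allowed:
                violations.append(Violation(seq.id, pos, sym))
    return ValidationResult(tuple(violations))


def generate_random_sequences(
    n: int, length: int, alphabet: Alphabet, seed: int
) -> SequenceSet:
    """Synthesize ``n`` independent uniform-random sequences of the given length.

    Identical ``(n, length, alphabet, seed)`` yields byte-identical output;
    this generator is the package's stand-in for downloading real sequence
    data, so every test and demonstration is reproducible offline.
    """
    if n < 2:
        raise ParameterError(f"need n >= 2 sequences, got {n}")
    if length < 1:
        raise ParameterError(f"need length >= 1, got {length}")
    rng = random.Random(seed)
    seqs = tuple(
        BioSequence(f"s{i + 1}", "".join(rng.choice(alphabet.symbols) for _ in range(length)))
        for i in range(n)
    )
    return SequenceSet(alphabet, seqs)


def write_report(report: ResultReport, path: PathLike) -> None:
    """Write a plain-text result report: one MLCS per line (sorted), then totals."""
    path = Path(path)
    lines = list(report.mlcs_strings)
    lines.append(f"length: {report.length_L}")
    lines.append(f"count: {report.count}")
    lines.append(f"paths: {report.path_count}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}")


def write_fasta(seqs: SequenceSet, path: PathLike) -> None:
    """Write a sequence set back out as FASTA (used by the fixture generator)."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            for seq in seqs.sequences:
                fh.write(f">{seq.id}\n{seq.residues}\n")
    except OSError as exc:
        raise InputError(f"cannot write FASTA to {path}: {exc}")
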