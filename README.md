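# mlcskit

Exact enumeration of **all** longest common subsequences shared by two or
more DNA or protein sequences (the MLCS problem), for sequence analysts who
need every co-optimal conserved subsequence — not just one of them — plus
the machinery to prove the answer is right.

A subsequence is an ordered, not necessarily contiguous, selection of
residues; the MLCS of n sequences is the set of all longest strings that
are subsequences of every input. The problem is NP-hard in n, but the
dominant-point family of algorithms solves practical instances exactly by
never materialising the full dynamic-programming lattice:

1. **Legality check** — residues validated against the declared alphabet.
2. **Successor tables** — per sequence, `next_occ(c, j)` = first position
   after j carrying symbol c, making match-point generation O(1) per symbol.
3. **Level-wise expansion with pruning** — match points P = [p_1...p_n]
   (all sequences share one symbol at those positions) at level k generate
   level k+1; duplicates merge and strictly dominated points (another
   candidate smaller in *every* coordinate) are discarded, which provably
   removes only points lying on no longest path. The classic weak
   ("k-dominant") filter is also available, but it can drop co-optimal
   strings and is therefore not the enumeration default (see
   `docs/methods.md` for the two-line counterexample).
4. **DAG construction** — retained points and parent links form a leveled
   acyclic graph; dead ends are trimmed, so every source-to-sink path has
   exactly L edges, L being the MLCS length.
5. **Backtracking** — depth-first traversal spells one common subsequence
   per path; the report lists the distinct strings (sorted), their common
   length L, their count, and the raw path count.

Also included: pairwise DP baselines (full-matrix and two-row linear-space
length), exhaustive pairwise LCS enumeration, an unpruned n-dimensional
brute-force oracle that shares no code with the engine, an admissible
heuristic pruning mode (`hf`) that is exactness-preserving by construction,
and a seeded random-sequence generator so everything runs offline.

## Worked example

The classic pair `ABCBDAB` / `BDCABA` has three distinct longest common
subsequences of length 4. (`B` is not a standard amino-acid code, so it is
admitted explicitly.)

```
$ printf '>s1\nABCBDAB\n>s2\nBDCABA\n' > pair.fasta
$ mlcs search pair.fasta --extend-alphabet B
BCAB
BCBA
BDAB
length: 4
count: 3
paths: 3
```

Three strings, each of length 4 (`length`), `count: 3` distinct strings,
and `paths: 3` source-to-sink DAG paths (here no two paths spell the same
string). The same instance through `--algorithm dp2` (pairwise DP) or
`--algorithm brute` (lattice oracle) prints the identical report.

A three-sequence DNA run from the built-in generator:

```
$ mlcs generate --n 3 --length 12 --alphabet dna --seed 42 --out trio.fasta
$ mlcs search trio.fasta
CCAAT
CCATA
length: 5
count: 2
paths: 2
```

The two length-5 strings are the complete MLCS set of the three random
sequences. `mlcs selftest --seed 1 --trials 10` cross-checks the engine
against the brute-force oracle on random instances and prints
`selftest passed (10 trials)`.

Library use mirrors the CLI:

```python
from mlcskit import Alphabet, generate_random_sequences, \
    run_dominant_point_search, backtrack_enumerate

seqs = generate_random_sequences(3, 12, Alphabet.dna(), seed=42)
report = backtrack_enumerate(run_dominant_point_search(seqs))
report.mlcs_strings   # ('CCAAT', 'CCATA')
report.length_L       # 5
```

## Layout

| Module | Contents |
| --- | --- |
| `mlcskit.sequences_io` | alphabets, FASTA parsing, validation, generator, reports |
| `mlcskit.successor_table` | successor tables, suffix counts, match-point generation |
| `mlcskit.dominant_points` | dominance, pruning, level expansion, the search |
| `mlcskit.mlcs_graph` | DAG trimming, backtracking, path counting, verification |
| `mlcskit.baselines` | pairwise DP, linear-space length, brute-force oracle |
| `mlcskit.assembly` / `mlcskit.cli` | component registry, pipeline, `mlcs` CLI |
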