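# Methods

## Problem and model

Given n >= 2 sequences over a fixed residue alphabet (4 nucleotides or the
20 standard amino acids), the multiple longest common subsequence (MLCS)
problem asks for *every* distinct longest string that is a subsequence —
ordered, not necessarily contiguous — of all n inputs. mlcskit solves it
exactly with the dominant-point family of algorithms and keeps two
independent baselines (pairwise dynamic programming, and an unpruned
n-dimensional lattice DP) alongside for cross-checking.

The state space is the position lattice: a point P = [p_1, ..., p_n]
assigns one 1-based position per sequence, with 0 the virtual
"before-the-start" coordinate. P is a **match point** when all n sequences
carry the same symbol at their respective positions. Match points reached
after k expansion steps sit at **level k**: each spells a common
subsequence of length k along its parent chain. The search is
level-synchronous breadth-first: level k+1 is generated from level k
through per-sequence successor tables, pruned, and the process repeats
until a level comes back empty; the last non-empty level is the MLCS
length L. Retained points and their parent links form a leveled DAG whose
source-to-sink paths (exactly L edges each) spell the MLCS set, enumerated
by depth-first backtracking.

## Successor tables

For each sequence, `next_occ(c, j)` is the smallest position > j carrying
symbol c, stored densely as a (sigma x (length+1)) integer array built in
one backward sweep. "No further occurrence" is an explicit sentinel (-1),
never 0: position 0 is reserved for the virtual source coordinate, which
avoids the classic off-by-one in successor-table code. Tables are immutable
after construction. A companion suffix-count table (occurrences of each
symbol strictly after each position, same backward recurrence) feeds the
heuristic pruning bound.

## Pruning: why strict dominance is the default

P weakly dominates Q when p_i <= q_i in every coordinate, strictly when
p_i < q_i in every coordinate. Candidate level sets are pruned as follows:

* duplicate coordinate vectors collapse into one point whose parent set is
  the union of the duplicates' parents (lexicographically first
  representative kept);
* with `dominance="strong"` (default), a candidate strictly dominated by
  another candidate is discarded. This is provably lossless for exhaustive
  enumeration: if Q < P coordinatewise at the same level, then any
  extension u of P is also an extension of Q, *and* Q can additionally
  match P's own symbol first — so every string through P is strictly
  shorter than some string through Q, and P lies on no longest path.
* with `dominance="weak"`, a candidate weakly dominated by any *other*
  candidate is discarded — the textbook "k-dominant point" filter (the
  level-k Pareto frontier).

The weak filter preserves the length L but **not** the full string set,
which is why it is not the default. Counterexample: for the pair
`ABA` / `BAA` the MLCS set is {`AA`, `BA`}. At level 2 the endpoint of
`AA` is [3,3] and the endpoint of `BA` is [3,2]; [3,2] weakly dominates
[3,3] (they share the first coordinate, both spell final symbol A), so the
weak filter deletes [3,3] and the string `AA` — a genuine MLCS — is lost.
Weak-but-not-strict dominance can only occur between points matching the
same symbol (a shared coordinate forces a shared residue), and exactly
those ties carry co-optimal alternative spellings. Both predicates are
exposed; the unit suite pins the weak filter's classical behaviour and the
enumeration suite proves the strong filter equals the brute-force oracle.

## DAG construction and enumeration

Retained points at levels below L can be dead ends (no surviving
children). A backward sweep from the level-L sinks keeps only nodes on
some source-to-sink path; parents of kept nodes are always kept because
expansion only ever grows from retained points. After trimming, every edge
raises the level by exactly 1 and every source-to-sink path has exactly L
edges. Backtracking is an iterative DFS visiting children in
(symbol, positions) order, so output is reproducible; a seeded
shuffle hook exists purely to let tests demonstrate that the deduplicated
string set is traversal-order invariant. The report carries both the
distinct-string count (the headline "number of MLCS" — users see strings,
so duplicate-spelling paths would be indistinguishable) and the raw path
count, which is independently recomputed by memoized per-node summation
and must agree with the DFS tally.

## Heuristic (hf) pruning

The hf mode adds an admissible-bound filter in front of dominance pruning.
The bound for a point P is sum over symbols c of min over sequences i of
the remaining occurrences of c after p_i; no common subsequence extending
P can be longer, so the bound never underestimates. The lower bound it is
tested against is the length of a greedy common subsequence (from the
source, repeatedly take the symbol whose successor vector has the smallest
coordinate sum, ties broken in alphabet order) computed once at search
start. A candidate at level k+1 is discarded when
(k+1) + bound < lower_bound: such a point cannot reach even the greedy
length, hence lies on no longest path, hence hf and pf produce identical
reports — a property the test suite asserts instance by instance rather
than assumes.

## Baselines and the oracle

For n = 2 the package carries the standard full-matrix LCS dynamic
program, a two-row variant computing the same length in linear space, and
memoized backtracking that enumerates all distinct pairwise LCS. The
ground-truth oracle for any n fills the complete (len_1+1) x ... x
(len_n+1) lattice with the classic recurrence and backtracks exhaustively;
it shares no code with the dominant-point engine (no successor tables, no
pruning) precisely so the two cannot share a bug. Its cost is the full
lattice, so it is budget-gated and usable only at small scale — which is
its job. Its report sets path_count equal to the distinct-string count,
since no DAG exists on that route.

## Validation and input handling

FASTA input is read with Biopython, uppercased, and tagged dna iff every
residue is one of A/C/G/T (else protein). The legality check reports
violations as data — (sequence id, 1-based position, symbol) — rather than
raising, so a caller can display all of them; the pipeline turns a
non-empty violation list into an input error. No repair is performed: `U`
in a DNA set is a violation, not a T. Ambiguity codes are rejected unless
explicitly admitted via alphabet extension (`--extend-alphabet`), because
dominant-point matching assumes exact symbol equality; this is also how
non-biological demonstration strings containing `B` are run. An empty
record is reported as a violation at position 0.

## Synthetic data

`generate_random_sequences(n, length, alphabet, seed)` draws residues
i.i.d. uniform over the alphabet — byte-identical for identical arguments.
Uniform random sequences are the standard stress model for MLCS engines
(they maximise match-point density disorder) but they carry no homology,
conservation blocks, indel structure or skewed composition; passing tests
on them demonstrates algorithmic correctness and scaling behaviour, not
biological insight on real gene families. Test problem sizes were chosen
so the exponential oracle stays comfortable: the oracle-equivalence suite
uses 200 instances with n in {2,3,4} and lengths 4-12 on both alphabets
(lattice <= 13^4 cells), and the pairwise-consistency suite uses 200 DNA
pairs of lengths 20-200.

## Numerical and design choices

* Budgets, not crashes: the search caps retained nodes (default 10^6) and
  enumeration caps paths/strings (default 10^6); exceeding either raises a
  clean resource error naming the point of failure.
* All coordinates are small non-negative integers — no floating point
  anywhere, so "tolerance" questions do not arise; every comparison in the
  suite is exact equality.
* Tie-breaks are all lexicographic ((symbol, positions) child order,
  lexicographic duplicate-representative choice, alphabet-order greedy
  ties), making every surface byte-deterministic.
* Degenerate inputs: disjoint alphabets yield L=0 and an empty report;
  identical sequences yield a single chain; n < 2 and empty sequences are
  rejected up front.
* The component registry maps feature names (algorithm, prune_mode,
  result_op) to implementations so variants are assembled by registration;
  the CLI is a thin shell over it.

## Known limitations

* The brute-force oracle and full enumeration are exponential by nature;
  the engine is exact, so adversarial inputs (many near-identical long
  sequences) can legitimately exhaust budgets.
* Weak-dominance mode exists for study and length computation only; see
  the counterexample above.
* No approximate/heuristic search (ant colony, beam search) is included;
  the only heuristic element, hf, is exactness-preserving by construction.
* Pairwise linear-space mode computes length only; it does not reconstruct
  a witness string in linear space.
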