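"""Dominance, pruning, level expansion and the full dominant-point search."""

import random

import pytest
from hypothesis import given, strategies as st

from mlcskit import (
    Alphabet,
    BudgetExceededError,
    ConfigError,
    LevelSet,
    MatchPoint,
    ParameterError,
    PruneOptions,
    backtrack_enumerate,
    brute_force_mlcs,
    build_suffix_counts,
    dominates,
    expand_level,
    generate_random_sequences,
    prune_minima,
    run_dominant_point_search,
    upper_bound,
)
from mlcskit.sequences_io import BioSequence, SequenceSet
from mlcskit.successor_table import build_successor_tables


def make_set(*residues, alphabet=None):
    alphabet = alphabet or Alphabet.protein().extended("B")
    return SequenceSet(
        alphabet, tuple(BioSequence(f"s{i}", r) for i, r in enumerate(residues))
    )


class TestDominates:
    @pytest.mark.parametrize(
        "p,q,weak,strict",
        [
            ((1, 2), (2, 2), True, False),
            ((1, 2), (2, 1), False, False),
            ((1, 2), (1, 2), True, False),
            ((1, 1), (2, 2), True, True),
        ],
    )
    def test_pairs(self, p, q, weak, strict):
        assert dominates(p, q) == (weak, strict)

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError):
            dominates((1, 2), (1, 2, 3))


def mp(vec, level=1, symbol="A", parents=None):
    return MatchPoint(tuple(vec), level, symbol, parents or set())


class TestPruneMinima:
    def test_weak_mode_removes_weakly_dominated(self):
        out = prune_minima([mp([1, 2]), mp([2, 1]), mp([2, 2])], dominance="weak")
        assert [p.positions for p in out] == [(1, 2), (2, 1)]

    def test_strong_mode_keeps_weakly_dominated_cooptimal(self):
        # (2,2) shares no strict domination with (1,2)/(2,1): retained
        out = prune_minima([mp([1, 2]), mp([2, 1]), mp([2, 2])], dominance="strong")
        assert [p.positions for p in out] == [(1, 2), (2, 1), (2, 2)]
        out = prune_minima([mp([1, 1]), mp([2, 2])], dominance="strong")
        assert [p.positions for p in out] == [(1, 1)]

    def test_singleton_survives(self):
        assert [p.positions for p in prune_minima([mp([1, 2])])] == [(1, 2)]

    def test_duplicates_collapse_with_merged_parents(self):
        pa, pb = mp([0, 0], level=0, symbol=None), mp([0, 1], level=0, symbol=None)
        out = prune_minima([mp([1, 2], parents={pa}), mp([1, 2], parents={pb})])
        assert len(out) == 1
        assert out[0].parents == {pa, pb}

    def test_mixed_levels_rejected(self):
        with pytest.raises(ParameterError):
            prune_minima([mp([1, 2], level=1), mp([2, 3], level=2)])

    @given(st.integers(0, 10**6))
    def test_matches_all_pairs_oracle(self, seed):
        """Both modes agree with a brute-force all-pairs dominance check on
        random candidate sets (dimension <= 5, coordinates <= 20)."""
        rng = random.Random(seed)
        n = rng.randint(2, 5)
        vecs = {tuple(rng.randint(1, 20) for _ in range(n)) for _ in range(rng.randint(1, 15))}
        cands = [mp(v) for v in vecs]
        for mode in ("weak", "strong"):
            got = {p.positions for p in prune_minima(cands, dominance=mode)}
            idx = 1 if mode == "strong" else 0
            want = {
                v
                for v in vecs
                if not any(u != v and dominates(u, v)[idx] for u in vecs)
            }
            assert got == want


class TestUpperBound:
    def test_ab_ba_from_source(self):
        seqs = make_set("AB", "BA")
        counts = build_suffix_counts(seqs)
        assert upper_bound((0, 0), counts) == 2

    def test_zero_at_sequence_ends(self):
        seqs = make_set("AB", "BA")
        counts = build_suffix_counts(seqs)
        assert upper_bound((2, 2), counts) == 0

    def test_repeated_symbol(self):
        seqs = make_set("AAA", "AAA")
        counts = build_suffix_counts(seqs)
        assert upper_bound((1, 1), counts) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_admissibility_on_random_instances(self, dna, seed):
        """The bound from the source never undershoots the true MLCS length."""
        seqs = generate_random_sequences(3, 10, dna, seed=seed)
        counts = build_suffix_counts(seqs)
        truth = brute_force_mlcs(seqs).length_L
        assert upper_bound(tuple(0 for _ in range(3)), counts) >= truth


class TestExpandLevel:
    def source_level(self, n):
        return LevelSet(0, [MatchPoint(tuple(0 for _ in range(n)), 0)])

    def test_ab_ba_first_level(self):
        seqs = make_set("AB", "BA")
        tables = build_successor_tables(seqs)
        out = expand_level(self.source_level(2), tables, PruneOptions())
        assert {p.positions for p in out.points} == {(1, 2), (2, 1)}
        assert out.k == 1

    def test_empty_level_stays_empty(self):
        seqs = make_set("AB", "BA")
        tables = build_successor_tables(seqs)
        assert expand_level(LevelSet(3, []), tables, PruneOptions()).points == []

    def test_single_successor_chain(self):
        seqs = make_set("AA", "AA")
        tables = build_successor_tables(seqs)
        lvl1 = LevelSet(1, [mp([1, 1], level=1)])
        out = expand_level(lvl1, tables, PruneOptions())
        assert [p.positions for p in out.points] == [(2, 2)]
        assert out.points[0].level == 2

    def test_hf_without_counts_is_config_error(self):
        seqs = make_set("AB", "BA")
        tables = build_successor_tables(seqs)
        with pytest.raises(ConfigError):
            expand_level(self.source_level(2), tables, PruneOptions(mode="hf"))

    def test_children_record_parents(self):
        seqs = make_set("AB", "BA")
        tables = build_successor_tables(seqs)
        src = self.source_level(2)
        out = expand_level(src, tables, PruneOptions())
        for child in out.points:
            assert child.parents == set(src.points)


class TestRunSearch:
    def test_worked_pair_length(self, worked_pair):
        assert run_dominant_point_search(worked_pair).L == 4

    def test_identical_sequences_single_chain(self, dna):
        seqs = make_set("ACGT", "ACGT", "ACGT", alphabet=dna)
        graph = run_dominant_point_search(seqs)
        assert graph.L == 4
        assert all(len(lv) == 1 for lv in graph.levels)

    def test_disjoint_symbols_bare_source(self, dna):
        graph = run_dominant_point_search(make_set("AAA", "CCC", alphabet=dna))
        assert graph.L == 0
        assert graph.node_count == 1

    def test_node_budget_names_level(self, dna):
        seqs = generate_random_sequences(2, 40, dna, seed=1)
        with pytest.raises(BudgetExceededError, match="level"):
            run_dominant_point_search(seqs, node_budget=3)

    def test_stats_log_is_per_level_tsv(self, dna, tmp_path):
        seqs = generate_random_sequences(2, 15, dna, seed=3)
        path = tmp_path / "stats.tsv"
        with path.open("w") as fh:
            graph = run_dominant_point_search(seqs, stats_file=fh)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "level\tcandidates\tretained"
        assert len(lines) >= graph.L + 1

    @pytest.mark.parametrize("seed", range(8))
    def test_parent_child_monotonicity(self, dna, seed):
        """Every coordinate strictly increases along every parent->child edge."""
        seqs = generate_random_sequences(3, 10, dna, seed=seed)
        graph = run_dominant_point_search(seqs)
        for parent, kids in graph.children.items():
            for kid in kids:
                assert all(k > p for k, p in zip(kid.positions, parent.positions))
                assert kid.level == parent.level + 1

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_pf_and_hf_reports_identical(self, dna, n, seed):
        """The admissible-bound (hf) filter never changes the result."""
        seqs = generate_random_sequences(n, 4 + (seed % 12), dna, seed=1000 * n + seed)
        pf = backtrack_enumerate(run_dominant_point_search(seqs, PruneOptions("pf")))
        hf = backtrack_enumerate(run_dominant_point_search(seqs, PruneOptions("hf")))
        assert pf == hf

    @pytest.mark.parametrize("seed", range(8))
    def test_weak_dominance_preserves_length(self, dna, seed):
        """The classic k-dominant filter finds the same maximal length L (its
        level sets are the Pareto frontiers), even where it thins the string set."""
        seqs = generate_random_sequences(3, 10, dna, seed=seed)
        strong = run_dominant_point_search(seqs, PruneOptions(dominance="strong"))
        weak = run_dominant_point_search(seqs, PruneOptions(dominance="weak"))
        assert strong.L == weak.L

    def test_weak_dominance_can_lose_cooptimal_strings(self, protein):
        """The documented counterexample: for ABA/BAA the MLCS set is
        {AA, BA}; weak pruning discards the endpoint spelling AA because it is
        weakly dominated by the endpoint of BA."""
        seqs = make_set("ABA", "BAA", alphabet=protein.extended("B"))
        strong = backtrack_enumerate(run_dominant_point_search(seqs))
        weak = backtrack_enumerate(
            run_dominant_point_search(seqs, PruneOptions(dominance="weak"))
        )
        assert strong.mlcs_strings == ("AA", "BA")
        assert weak.mlcs_strings == ("BA",)
        assert brute_force_mlcs(seqs).mlcs_strings == ("AA", "BA")
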