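"""Component registry and end-to-end pipeline assembly.

Algorithm variants are assembled from registered components rather than
hard-wired: the registry maps a feature kind ("algorithm", "prune_mode") and
a name to an implementation, so a new variant is added by registration, not
by editing the pipeline.  ``assemble_and_run`` executes the canonical call
sequence: read -> legality check -> successor tables -> search -> backtrack
-> report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Optional

import yaml

from .baselines import brute_force_mlcs, dp_enumerate_all_lcs
from .dominant_points import (
    DEFAULT_NODE_BUDGET,
    PruneOptions,
    run_dominant_point_search,
)
from .errors import ConfigError, InputError
from .mlcs_graph import DEFAULT_ENUM_BUDGET, backtrack_enumerate, verify_result
from .sequences_io import (
    Alphabet,
    ResultReport,
    SequenceSet,
    generate_random_sequences,
    parse_fasta,
    validate_sequences,
    write_report,
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; accepted from CLI flags and/or a YAML file."""

    input_path: Optional[str] = None
    output_path: Optional[str] = None
    algorithm: str = "dominant"
    prune: str = "pf"
    alphabet: str = "auto"  # dna | protein | auto
    extend_alphabet: str = ""  # extra symbols admitted beyond the canonical set
    seed: int = 0
    node_budget: int = DEFAULT_NODE_BUDGET
    enum_budget: int = DEFAULT_ENUM_BUDGET
    stats_path: Optional[str] = None
    dot_path: Optional[str] = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in _REGISTRY["algorithm"]:
            raise ConfigError(
                f"unknown algorithm {self.algorithm!r}; "
                f"registered: {sorted(_REGISTRY['algorithm'])}"
            )
        if self.prune not in _REGISTRY["prune_mode"]:
            raise ConfigError(
                f"unknown prune mode {self.prune!r}; registered: {sorted(_REGISTRY['prune_mode'])}"
            )
        if self.alphabet not in ("dna", "protein", "auto"):
            raise ConfigError(f"unknown alphabet {self.alphabet!r}")


def load_config(path: str, overrides: dict) -> RunConfig:
    """Build a RunConfig from a YAML file; explicit ``overrides`` win."""
    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as exc:
        raise InputError(f"cannot read config file {path}: {exc}")
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys in {path}: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Component registry

Algorithm = Callable[[SequenceSet, RunConfig], ResultReport]

_REGISTRY: dict[str, dict[str, object]] = {
    "algorithm": {},
    "prune_mode": {},
    "dp_mode": {},
    "result_op": {},
}


def register(kind: str, name: str, impl: object) -> None:
    if kind not in _REGISTRY:
        raise ConfigError(f"unknown component kind {kind!r}")
    _REGISTRY[kind][name] = impl


def get_component(kind: str, name: str) -> object:
    try:
        return _REGISTRY[kind][name]
    except KeyError:
        raise ConfigError(f"no {kind} component registered under {name!r}")


def _run_dominant(seqs: SequenceSet, config: RunConfig) -> ResultReport:
    opts: PruneOptions = get_component("prune_mode", config.prune)  # type: ignore[assignment]
    stats_fh = open(config.stats_path, "w") if config.stats_path else None
    try:
        graph = run_dominant_point_search(
            seqs, opts, node_budget=config.node_budget, stats_file=stats_fh
        )
    finally:
        if stats_fh:
            stats_fh.close()
    if config.dot_path:
        Path(config.dot_path).write_text(graph.to_dot())
    return backtrack_enumerate(graph, enum_budget=config.enum_budget)


def _run_dp2(seqs: SequenceSet, config: RunConfig) -> ResultReport:
    if seqs.n != 2:
        raise ConfigError(f"algorithm dp2 needs exactly 2 sequences, got {seqs.n}")
    s1, s2 = seqs.sequences
    found = sorted(dp_enumerate_all_lcs(s1, s2, budget=config.enum_budget))
    length = len(found[0]) if found else 0
    if found == [""]:
        found, length = [], 0
    return ResultReport(tuple(found), length, len(found), len(found))


def _run_brute(seqs: SequenceSet, config: RunConfig) -> ResultReport:
    return brute_force_mlcs(
        seqs, lattice_budget=config.node_budget, enum_budget=config.enum_budget
    )


register("algorithm", "dominant", _run_dominant)
register("algorithm", "dp2", _run_dp2)
register("algorithm", "brute", _run_brute)
register("prune_mode", "pf", PruneOptions(mode="pf"))
register("prune_mode", "hf", PruneOptions(mode="hf"))
register("result_op", "report", write_report)


def resolve_alphabet(seqs: SequenceSet, config: RunConfig) -> SequenceSet:
    """Re-tag a parsed set with the configured alphabet, plus any extension."""
    if config.alphabet != "auto":
        alpha = Alphabet.from_name(config.alphabet)
    else:
        alpha = seqs.alphabet
    if config.extend_alphabet:
        alpha = alpha.extended(config.extend_alphabet)
    return SequenceSet(alpha, seqs.sequences)


def assemble_and_run(config: RunConfig) -> ResultReport:
    """The canonical pipeline.  Deterministic: identical config plus input
    yields a byte-identical report file."""
    if not config.input_path:
        raise ConfigError("no input path configured")
    seqs = parse_fasta(config.input_path, "auto")
    seqs = resolve_alphabet(seqs, config)
    verdict = validate_sequences(seqs)
    if not verdict.ok:
        v = verdict.violations[0]
        raise InputError(
            f"sequence legality check failed ({len(verdict.violations)} violation(s)); "
            f"first: sequence {v.sequence_id!r} position {v.position} symbol {v.symbol!r}"
        )
    algorithm: Algorithm = get_component("algorithm", config.algorithm)  # type: ignore[assignment]
    report = algorithm(seqs, config)
    if config.output_path:
        write_report(report, config.output_path)
    return report


# ---------------------------------------------------------------------------
# Self-test: dominant engine vs. brute-force oracle on random instances


@dataclass(frozen=True)
class SelftestVerdict:
    passed: bool
    trials: int
    warning: str = ""
    counterexample: str = ""


def selftest(seed: int, trials: int = 25) -> SelftestVerdict:
    """Compare the dominant-point pipeline against the brute-force oracle on
    ``trials`` random small instances (n in 2..4, lengths 4..12, dna)."""
    import random as _random

    if trials == 0:
        return SelftestVerdict(True, 0, warning="0 trials requested: vacuous pass")
    rng = _random.Random(seed)
    alpha = Alphabet.dna()
    for t in range(trials):
        n = rng.choice([2, 3, 4])
        length = rng.randint(4, 12)
        seqs = generate_random_sequences(n, length, alpha, seed=rng.randrange(2**31))
        graph = run_dominant_point_search(seqs, PruneOptions())
        got = backtrack_enumerate(graph)
        want = brute_force_mlcs(seqs)
        ok = (
            got.length_L == want.length_L
            and got.mlcs_strings == want.mlcs_strings
            and verify_result(got, seqs).ok
        )
        if not ok:
            return SelftestVerdict(
                False,
                trials,
                counterexample=(
                    f"trial {t}: sequences {seqs.residue_strings()}; "
                    f"dominant L={got.length_L} strings={got.mlcs_strings}; "
                    f"oracle L={want.length_L} strings={want.mlcs_strings}"
                ),
            )
    return SelftestVerdict(True, trials)
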