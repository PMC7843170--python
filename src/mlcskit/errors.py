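"""Exception hierarchy with stable CLI exit codes.

Exit codes: 2 input (files, sequences, parameters), 3 configuration,
4 graph integrity, 5 resource budget. 0 is success; 1 is reserved for
unexpected failures.
"""


class MLCSError(Exception):
    """Base class for all mlcskit errors."""

    exit_code = 1


class InputError(MLCSError):
    """Bad input data: missing/malformed files, illegal residues."""

    exit_code = 2


class ParameterError(InputError):
    """A function precondition was violated (dimension, range, cardinality)."""


class ConfigError(MLCSError):
    """An inconsistent or unknown run configuration."""

    exit_code = 3


class GraphIntegrityError(MLCSError):
    """The dominant-point DAG violates its structural invariants."""

    exit_code = 4


class BudgetExceededError(MLCSError):
    """A node or enumeration budget was exhausted before completion."""

    exit_code = 5
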