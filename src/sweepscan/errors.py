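"""Exception hierarchy shared across the package.

Exit codes follow the CLI contract: 2 for bad inputs or configuration,
3 for numerical/computation failures.
"""


class SweepscanError(Exception):
    exit_code = 1


class InputError(SweepscanError):
    """Malformed or inconsistent user-supplied input."""

    exit_code = 2


class ConfigError(InputError):
    """Invalid simulation or run configuration."""


class AnnotationError(InputError):
    """SNP allele inconsistent with the supplied reference sequence."""


class ComputationError(SweepscanError):
    """A statistic is undefined on the given data (e.g. zero spread)."""

    exit_code = 3
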