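"""Exception hierarchy.

``ConfigError`` covers user/configuration mistakes (CLI exit code 1),
``DataError`` covers problems with the data themselves (exit code 2).
"""

from __future__ import annotations


class DropquantError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DropquantError):
    """Invalid configuration; collects every problem found, not just the first."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


class DataError(DropquantError):
    """Malformed or unusable input data."""


class SaturatedWellError(DataError):
    """Every droplet is positive; the Poisson estimate diverges."""


class NoClusterStructureError(DataError):
    """A 1-D amplitude distribution has no resolvable two-cluster split."""
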