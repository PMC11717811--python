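"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ParameterError -> 2, InputError -> 3,
ComputationError (and subclasses) -> 4.
"""


class GliamigError(Exception):
    """Base class for all package errors."""


class ParameterError(GliamigError, ValueError):
    """A caller-supplied parameter is invalid."""


class InputError(GliamigError, OSError):
    """An input file or table is missing or malformed."""


class ComputationError(GliamigError, RuntimeError):
    """A computation could not produce a defined result."""


class CapacityError(ComputationError):
    """Synthetic-scene placement failed after bounded retries."""


class EmptyResultError(ComputationError):
    """An operation has no defined result on empty input."""
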