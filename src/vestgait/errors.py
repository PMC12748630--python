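"""Exception hierarchy.

All package-specific failures derive from :class:`VestgaitError` so callers
(and the CLI, which maps them to exit code 3) can catch one base class.
"""


class VestgaitError(Exception):
    """Base class for all vestgait errors."""


class ConfigurationError(VestgaitError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(VestgaitError):
    """A malformed on-disk artifact; the message names the file and column."""


class ContractError(VestgaitError):
    """A violated call contract (wrong placement, shape, empty input, ...)."""


class AlignmentError(VestgaitError):
    """Trials of one subject/task disagree in length or metadata."""


class UndefinedMetricError(VestgaitError):
    """A metric whose denominator is empty (e.g. accuracy of zero cycles)."""
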