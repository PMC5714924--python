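"""Exception hierarchy for nsclcfinder.

Every error raised on bad user input derives from :class:`NsclcFinderError`
so callers (and the CLI) can distinguish input problems from bugs.
"""


class NsclcFinderError(Exception):
    """Base class for all package errors."""


class SchemaError(NsclcFinderError):
    """A required column is missing or a file has the wrong shape."""


class RowParseError(NsclcFinderError):
    """A specific row of an input file could not be parsed (carries the line number)."""


class ValidationError(NsclcFinderError):
    """A value violates a domain contract (e.g. an unknown subtype label)."""


class ConfigurationError(NsclcFinderError):
    """A criteria/code-list configuration references something that does not exist."""


class ContractError(NsclcFinderError):
    """Two collections that must cover the same patients do not."""
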