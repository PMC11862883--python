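"""Exception hierarchy shared across the package."""


class MonosurfError(Exception):
    """Base class for all package errors."""


class InputError(MonosurfError, ValueError):
    """A caller supplied an invalid value or an ill-formed object."""


class TopologyError(MonosurfError, KeyError):
    """A chain topology references beads absent from the particle table."""


class ParseError(MonosurfError, ValueError):
    """A delimited-text table could not be parsed."""


class FormatError(MonosurfError, ValueError):
    """A coordinate file is malformed, truncated or unsupported."""
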