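"""Exception hierarchy for macpol."""


class MacpolError(Exception):
    """Base class for all macpol errors."""


class NetworkFormatError(MacpolError):
    """A network file (or in-memory network) violates the format contract."""


class AlignmentError(MacpolError):
    """A state vector does not align with the network it is used with."""


class ConfigurationError(MacpolError):
    """A simulation or network configuration is invalid."""


class EnumerationLimitError(MacpolError):
    """The network is too large for exhaustive state-space enumeration."""


class AuditError(MacpolError):
    """A census delta could not be reconciled against the event log."""


class RuleFormatError(MacpolError):
    """A reaction-rule table file violates the format contract."""
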