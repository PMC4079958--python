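"""Exception hierarchy shared by all flowindel modules."""


class FlowIndelError(Exception):
    """Base class for all errors raised by flowindel."""


class CigarError(FlowIndelError):
    """A read's CIGAR is malformed or inconsistent with its sequence."""


class BoundsError(FlowIndelError):
    """A coordinate or interval falls outside the reference sequence."""


class ContractError(FlowIndelError):
    """An operation was invoked with inputs violating its preconditions."""


class SchemaError(FlowIndelError):
    """An input record is missing a required field or is malformed."""


class ConfigError(FlowIndelError):
    """A configuration value is impossible or inconsistent."""


class EvidenceError(FlowIndelError):
    """A quantity is undefined because the supporting evidence is absent
    (zero depth, empty pileup, zero trials)."""


class ValidationError(FlowIndelError):
    """Command-line level input validation failure."""
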