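"""Exception hierarchy.

Everything user-facing raises a subclass of :class:`GenesignalError` so the
CLI can separate user errors (exit 1) from internal failures (exit 2).
"""


class GenesignalError(Exception):
    """Base class for all errors raised by genesignal."""


class AlignmentError(GenesignalError):
    """Malformed alignment: ragged rows, duplicate taxa, illegal characters."""


class PartitionError(GenesignalError):
    """Malformed or inconsistent gene/partition map."""


class NewickError(GenesignalError):
    """Malformed Newick tree text."""


class ConstraintError(GenesignalError):
    """A clade constraint cannot be interpreted or applied on a tree."""


class FilterError(GenesignalError):
    """Sequence-inclusion filter removed every sequence."""


class ConfigError(GenesignalError):
    """Invalid pipeline run configuration."""
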