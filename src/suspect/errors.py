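"""Exception hierarchy shared by all modules."""


class SuspectError(Exception):
    """Base class for all package errors."""


class ParseError(SuspectError):
    """Malformed input file; message carries the offending line number."""


class FormatError(SuspectError):
    """Structurally invalid file (empty FASTA, ragged alignment, ...)."""


class ValidationError(SuspectError):
    """Value outside its domain (non-canonical residue, bad probability)."""


class ConsistencyError(SuspectError):
    """Cross-input disagreement, e.g. variant wild-type vs sequence."""


class BoundsError(SuspectError, IndexError):
    """1-based position outside the addressed sequence/matrix."""


class SchemaError(SuspectError):
    """Feature-matrix columns do not match what a model expects."""


class DegenerateInputError(SuspectError):
    """Input that makes the requested statistic undefined (single class,
    all-zero confusion table, zero pairwise distances)."""


class ConfigError(SuspectError):
    """Unresolvable or inconsistent run configuration."""
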