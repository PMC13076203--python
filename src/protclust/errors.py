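"""Exception hierarchy used across the package."""


class ProtclustError(Exception):
    """Base class for all package errors."""


class FormatError(ProtclustError):
    """Malformed input file (FASTA / TSV)."""


class IntegrityError(ProtclustError):
    """Violation of a structural invariant (partition property, unknown id, ...)."""


class ParameterError(ProtclustError):
    """Invalid parameter combination."""
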