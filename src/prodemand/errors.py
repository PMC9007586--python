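"""Exception types shared across the package."""


class ProdemandError(Exception):
    """Base class for all package errors."""


class FormatError(ProdemandError, ValueError):
    """A file is syntactically malformed (bad FASTA/GMT/TSV structure)."""


class ValidationError(ProdemandError, ValueError):
    """Well-formed input violates a semantic precondition."""
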