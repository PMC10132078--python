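"""Exception hierarchy shared across the pipeline."""


class IscoveryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IscoveryError):
    """Bad configuration: missing manifest columns, invalid parameters."""


class InputError(IscoveryError):
    """Input data that cannot be used: missing files, unresolvable paths."""


class FastqParseError(InputError):
    """Malformed FASTQ record; carries the 1-based record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class NonEncodableBaseError(IscoveryError):
    """Sequence contains a base outside {A,C,G,T} and cannot be 2-bit packed."""


class EmptyStoreError(IscoveryError):
    """No read survived the packing filters; downstream stages emit nothing."""


class InternalConsistencyError(IscoveryError):
    """Pipeline stages disagree (e.g. a candidate missing from clustering)."""
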