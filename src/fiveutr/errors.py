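"""Exception hierarchy shared across the package."""


class FiveUtrError(Exception):
    """Base class for all package-specific errors."""


class AnnotationError(FiveUtrError):
    """Structural problem in a gene annotation (e.g. CDS start outside exons)."""


class UnsupportedBiotypeError(FiveUtrError):
    """Operation requires a protein-coding transcript."""


class OutOfRangeError(FiveUtrError):
    """Genomic or transcript position outside the supported span."""


class InputError(FiveUtrError):
    """Malformed or empty user input."""


class ConfigurationError(FiveUtrError):
    """Invalid configuration value or missing required entity."""


class ContractViolation(FiveUtrError):
    """An operation was called outside its documented precondition."""


class ConsistencyError(FiveUtrError):
    """Cross-file references do not resolve (e.g. case cites unknown variant)."""


class PlanError(FiveUtrError):
    """The synthetic-data plan cannot be realized on the generated annotation."""
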