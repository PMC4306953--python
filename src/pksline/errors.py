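"""Exception hierarchy shared across the package."""


class PkslineError(Exception):
    """Base class for all package errors."""


class ValidationError(PkslineError):
    """A domain object or input file violates a structural invariant."""


class ClassificationError(PkslineError):
    """A signature, fingerprint or class token cannot be resolved."""


class DataError(PkslineError):
    """An enrichment table is malformed or numerically unusable."""


class AssemblyError(PkslineError):
    """A cluster cannot be turned into a linear product."""


class TilingError(PkslineError):
    """No valid unit tiling exists, or a size guard was exceeded."""


class GenerationError(PkslineError):
    """A synthetic-data generator cannot satisfy its constraints."""
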