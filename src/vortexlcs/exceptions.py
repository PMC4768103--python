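"""Exception hierarchy for vortexlcs."""


class VortexLCSError(Exception):
    """Base class for all package errors."""


class FormatError(VortexLCSError):
    """On-disk data malformed or internally inconsistent (shape mismatch, bad CSV)."""


class MetadataError(FormatError):
    """Required acquisition metadata (timing, spacing, units) missing or invalid."""


class ParseError(FormatError):
    """Malformed record in a text file; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(VortexLCSError):
    """A domain-type invariant is violated."""


class DomainError(VortexLCSError):
    """A query or argument lies outside the mathematically valid domain."""


class ConfigurationError(VortexLCSError):
    """Invalid or missing configuration value."""


class FitError(VortexLCSError):
    """A least-squares fit is degenerate (rank-deficient design)."""


class MeasurementError(VortexLCSError):
    """A measurement could not be taken (e.g. no voxel above threshold)."""


class GenerationError(VortexLCSError):
    """Synthetic-data generation produced an internally inconsistent dataset."""


class EmptyResultError(VortexLCSError):
    """An operation yielded no usable output (e.g. all seeds flagged)."""
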