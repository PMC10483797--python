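"""Exception hierarchy for proteoqc.

All package-specific failures derive from :class:`ProteoQCError` so callers
can catch one base class; most also derive from ``ValueError`` because they
signal invalid inputs or designs.
"""


class ProteoQCError(Exception):
    """Base class for all proteoqc errors."""


class ConfigurationError(ProteoQCError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class ValidationError(ProteoQCError, ValueError):
    """Input data (matrix, metadata, file) failed validation."""


class DesignError(ProteoQCError, ValueError):
    """The experimental design cannot support the requested statistic
    (e.g. SNR with fewer than two groups or two replicates)."""


class NormalizationError(ProteoQCError, ValueError):
    """Normalization impossible, e.g. a run with no present values."""


class DegenerateReplicatesError(ProteoQCError, ArithmeticError):
    """All replicates within each group coincide: the noise power is zero
    and the signal-to-noise ratio is infinite. Reported distinctly from a
    finite SNR so pipelines can flag it rather than emit ``inf``."""


class InsufficientDataError(ProteoQCError, ValueError):
    """Too few observations for the requested fit or summary."""
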