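"""Exception hierarchy shared by the scoring pipeline.

Separate classes exist so the CLI can map failure families onto stable
exit codes (usage vs data/format vs degenerate statistics).
"""


class RPSError(Exception):
    """Base class for all package-specific failures."""


class FormatError(RPSError):
    """Input file exists but violates the expected format (e.g. channel count)."""


class AlignmentError(RPSError):
    """Mask and image shapes disagree; no implicit resizing is performed."""


class GradabilityError(RPSError):
    """Image cannot yield a valid score (e.g. empty retinal background)."""


class ModelSchemaError(RPSError):
    """Persisted scoring-model file is missing required fields."""


class ModelVersionError(RPSError):
    """Persisted scoring-model file declares an unsupported format version."""


class FittingError(RPSError):
    """Too few points to fit the PCA scale."""


class DegenerateModelError(RPSError):
    """Zero-variance chromaticity cloud: no principal axis exists."""


class DegenerateStatisticsError(RPSError):
    """Reliability statistic undefined (e.g. zero within- and between-variance)."""


class StandardisationError(RPSError):
    """z-scoring requested on fewer than two values or zero spread."""
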