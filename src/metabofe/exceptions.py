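"""Exception hierarchy for the pipeline.

Every error raised by metabofe derives from :class:`MetabofeError`, so callers
(including the CLI) can distinguish pipeline failures from programming errors.
"""


class MetabofeError(Exception):
    """Base class for all metabofe errors."""


class ConfigurationError(MetabofeError):
    """Invalid simulation or pipeline configuration."""


class InputError(MetabofeError):
    """Invalid or inconsistent input data."""


class AlignmentError(InputError):
    """Identifiers do not line up across tables."""


class PedigreeError(InputError):
    """Pedigree is cyclic, unordered, or references unknown animals."""


class UndefinedTraitError(MetabofeError):
    """A derived trait is undefined for a record (e.g. FCR with BWG <= 0)."""


class CollinearityError(MetabofeError):
    """Design matrix is rank deficient."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class DegenerateSampleError(InputError):
    """A sample carries no signal (e.g. all-zero intensity row)."""

    def __init__(self, message: str, bird_ids=None):
        super().__init__(message)
        self.bird_ids = list(bird_ids) if bird_ids is not None else []


class EmptyPanelError(InputError):
    """A filtering step removed every feature."""


class TransformError(MetabofeError):
    """A numeric transform received out-of-domain values."""


class StratificationError(InputError):
    """Cross-validation folds cannot keep both classes in every training set."""


class ModelError(MetabofeError):
    """A statistical model cannot be formed or is degenerate."""
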