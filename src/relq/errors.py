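"""Exception types raised by the pipeline."""


class RelqError(Exception):
    """Base class for all errors raised by this package."""


class UnparseableFileError(RelqError):
    """No candidate delimiter splits the header into at least two fields."""


class MissingColumnError(RelqError):
    """A required canonical column (sample, target, cq) could not be resolved."""


class DuplicateWellError(RelqError):
    """The same well position occurs twice on one plate."""


class ModeMismatchError(RelqError):
    """Single-plate mode was requested with more than one input file."""


class MissingIPCError(RelqError):
    """The inter-plate calibrator sample is absent from a plate."""


class UnknownReferenceError(RelqError):
    """A named reference gene matches no target in the data."""


class UnknownCalibratorError(RelqError):
    """The calibrator sample is absent from the quantification table."""


class UnknownControlError(RelqError):
    """The control sample for significance testing is absent."""


class ConfigError(RelqError):
    """An invalid or inconsistent run configuration."""
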