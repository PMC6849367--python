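"""Exception hierarchy shared across the pipeline.

Every error raised on invalid user input derives from :class:`M6afgkError`
so the command-line layer can catch one type and exit non-zero.
"""


class M6afgkError(Exception):
    """Base class for all validation and configuration errors."""


class InvalidAlphabetError(M6afgkError):
    """A character outside {A,C,G,U,T} (any case) was found in a sequence."""


class LengthError(M6afgkError):
    """A record's sequence length does not match the corpus window length."""


class CentralSiteError(M6afgkError):
    """The central position of a window is not adenosine."""


class ConfigurationError(M6afgkError):
    """An invalid parameter combination (gamma, k, span, threshold, ...)."""


class EmptyCorpusError(M6afgkError):
    """An operation that needs sequences received none."""


class FeatureMismatchError(M6afgkError):
    """Vector/model dimensions do not match the feature set they claim."""


class LabelError(M6afgkError):
    """Labels are not binary 0/1."""


class DegenerateTrainingError(M6afgkError):
    """Training data contains a single class."""


class DivergenceError(M6afgkError):
    """Gradient descent produced non-finite cost or parameters."""


class DegenerateRocError(M6afgkError):
    """ROC/AUROC requested with only one class present."""


class StratificationError(M6afgkError):
    """A class has fewer members than the number of CV folds."""
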