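"""Exception types shared across the package."""


class PleurascanError(Exception):
    """Base class for all package-specific errors."""


class MissingPathError(PleurascanError, FileNotFoundError):
    """Input path does not exist."""


class EmptyClipError(PleurascanError):
    """No readable frames were found for a B-mode clip."""


class FrameShapeMismatchError(PleurascanError):
    """Frames of one clip do not share a single (height, width) shape."""


class MultiPageImageError(PleurascanError):
    """A multi-page file was given where a single image was expected."""


class ImageSizeError(PleurascanError, ValueError):
    """Image smaller than the minimum analyzable size."""


class IntensityRangeError(PleurascanError, ValueError):
    """Pixel intensities fall outside the normalized [0, 1] range."""


class MetadataError(PleurascanError, ValueError):
    """Malformed or out-of-vocabulary exam metadata."""


class RatingsTableError(PleurascanError, ValueError):
    """Malformed ratings table."""


class DuplicateRatingError(RatingsTableError):
    """The same (exam, rater) pair appears more than once."""


class LabelVocabularyError(RatingsTableError):
    """A label outside {positive, negative, indeterminate}."""


class PhantomConfigError(PleurascanError, ValueError):
    """Phantom configuration violates its invariants."""


class TooFewFramesError(PleurascanError):
    """Sliding analysis needs at least three frames."""


class InsufficientDepthError(PleurascanError):
    """Not enough rows below the pleural line for texture scoring."""


class SingleRaterError(PleurascanError, ValueError):
    """Adjudication requires at least two raters per exam."""


class UnmatchedExamsError(PleurascanError, ValueError):
    """Prediction and reference exam id sets do not align."""


class UndefinedKappaError(PleurascanError, ZeroDivisionError):
    """Cohen's kappa is undefined because expected agreement is 1."""


class UnknownStratumError(PleurascanError, KeyError):
    """Requested stratification variable is not recognized."""
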