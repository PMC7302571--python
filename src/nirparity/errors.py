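"""Exception hierarchy.

Every contract violation in the library raises a named subclass of
:class:`NirparityError` so callers (and the CLI) can report a precise
error class rather than a bare ``ValueError``.
"""


class NirparityError(Exception):
    """Base class for all errors raised by nirparity."""


# ---------------------------------------------------------------- spectra I/O
class SpectraFormatError(NirparityError):
    """A spectral table violates the on-disk format contract."""


class NonNumericWavelengthError(SpectraFormatError):
    """A column expected to be a wavelength header does not parse as a number."""


class DuplicateWavelengthError(SpectraFormatError):
    """Two columns claim the same wavelength."""


class RaggedRowError(SpectraFormatError):
    """A data row has a different number of fields than the header."""


class LabelValueError(NirparityError):
    """A parity label is outside the {0, 1} coding (after alias mapping)."""


# ---------------------------------------------------------------- model bundles
class BundleFormatError(NirparityError):
    """A model bundle file is truncated or not parseable."""


class BundleVersionError(BundleFormatError):
    """A model bundle was written by an incompatible format version."""


class BundleConsistencyError(BundleFormatError):
    """Dimensions recorded in a bundle do not agree with each other."""


# ---------------------------------------------------------------- preprocessing
class WindowCoverageError(NirparityError):
    """The wavelength grid does not cover the requested window."""


class GridSpacingError(NirparityError):
    """The wavelength grid is not sampled at 1 nm inside the window."""


class ReplicateError(NirparityError):
    """Replicate rows present under the 'forbid' replicate policy,
    or replicates with conflicting labels/cohorts."""


class NotFittedError(NirparityError):
    """A scaler (or other fitted transform) was applied before fitting."""


class LeakageError(NirparityError):
    """A statistic was about to be fitted on a held-out test partition."""


# ---------------------------------------------------------------- model training
class DimensionMismatchError(NirparityError):
    """Input feature dimension does not match the model."""


class ScalingRangeError(NirparityError):
    """Logistic-unit training input lies outside [0, 1]."""


class TrainingDivergedError(NirparityError):
    """Training produced a non-finite loss; carries diagnostics in args."""


class StepDimensionError(NirparityError):
    """Autoencoder step dimensions are not strictly decreasing."""


class TrainingInputError(NirparityError):
    """Training inputs contain NaN/inf or otherwise unusable values."""


class TrainingSingularError(NirparityError):
    """The damped normal matrix remained singular at maximum damping."""


class ConfigError(NirparityError):
    """An invalid configuration value; message lists every offending field."""


# ---------------------------------------------------------------- evaluation
class SplitError(NirparityError):
    """A train/test split cannot place at least one sample per partition."""


class DegenerateTestSetError(NirparityError):
    """The evaluated set is missing one of the two parity classes."""


class SingleClassError(NirparityError):
    """ROC/AUC requested on labels containing a single class."""


class WindowMismatchError(NirparityError):
    """Two cohorts do not share the same preprocessed wavelength window."""
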