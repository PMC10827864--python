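"""Exception hierarchy for the organocyte pipeline."""


class OrganocyteError(Exception):
    """Base class for all package-specific errors."""


class ImageIOError(OrganocyteError):
    """An image file could not be read or written."""


class FormatError(OrganocyteError):
    """Input data violates a structural expectation (channels, dtype, shape)."""


class SampleIDParseError(OrganocyteError):
    """A filename does not yield the four required sample-identity fields."""


class ConfigError(OrganocyteError):
    """A configuration value violates its invariant."""


class ParameterError(OrganocyteError):
    """An operation received parameters outside its valid domain."""


class TrainingError(OrganocyteError):
    """The pixel classifier cannot be trained from the given annotations."""


class PlacementError(OrganocyteError):
    """The scene generator could not place all requested objects.

    Carries ``achieved`` — the number of organoids successfully placed
    before giving up.
    """

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


class RegressionError(OrganocyteError):
    """Degenerate input to the area-regression fit."""
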