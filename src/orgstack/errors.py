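"""Exception types shared across the package."""


class OrgstackError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OrgstackError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyWellError(OrgstackError):
    """A rate was requested for a well with no detected objects.

    Raised instead of silently returning 0: an empty well is a failed
    acquisition or a dead culture, and both need the analyst's attention.
    """


class NoBackgroundError(OrgstackError):
    """The exclusion mask leaves no gel pixels to sample background from."""


class MissingMetadataError(OrgstackError):
    """A stack file lacks the physical calibration needed to interpret it."""
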