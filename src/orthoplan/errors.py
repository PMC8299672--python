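"""Exception types shared across the package."""


class OrthoplanError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometry(OrthoplanError):
    """Input geometry does not admit the requested construction.

    Raised e.g. when the Pi-Ns distance is not larger than the nasal-rest
    offset, when plane-defining points are collinear, or when the hinge
    axis would fall on or below the occlusal plane.
    """


class MissingLandmark(OrthoplanError):
    """A mandatory named landmark is absent from the input."""


class UnknownPivot(OrthoplanError):
    """A pivot name was referenced that does not exist on the jaw."""


class PivotMismatch(OrthoplanError):
    """Two jaws being compared do not carry the same pivot names."""


class MissingStage(OrthoplanError):
    """A planning stage (preop/postop jaw) required for export is absent."""


class FormatError(OrthoplanError):
    """A mesh or landmark file could not be parsed."""


class ConfigError(OrthoplanError):
    """A configuration file contains an unknown or invalid entry."""
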