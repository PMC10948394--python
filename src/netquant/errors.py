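"""Exception hierarchy for the netquant pipeline."""


class NetQuantError(Exception):
    """Base class for all netquant errors."""


class ValidationError(NetQuantError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""


class UnsupportedFormatError(NetQuantError):
    """Image file has a shape or dtype the pipeline does not handle."""


class ParameterError(NetQuantError):
    """A numeric parameter is outside its valid range."""


class NotBimodalError(NetQuantError):
    """The intensity histogram never reached exactly two modes.

    Carries the number of smoothing iterations performed before giving up.
    """

    def __init__(self, message: str, iterations: int = 0):
        super().__init__(message)
        self.iterations = iterations


class NoReferenceError(NetQuantError):
    """No ROIs are available to form a nuclear reference."""


class DegenerateReferenceError(NetQuantError):
    """Every ROI became a NET candidate; no condensed-nucleus reference exists."""


class InsufficientPairsError(NetQuantError):
    """Fewer than two complete pairs for a Bland-Altman comparison."""


class OvercrowdedSceneError(NetQuantError):
    """Synthetic object placement exhausted its attempt budget.

    Carries the object class that could not be placed.
    """

    def __init__(self, message: str, object_class: str = ""):
        super().__init__(message)
        self.object_class = object_class
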