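"""Exception and warning hierarchy for brachyqa."""


class BrachyQAError(Exception):
    """Base class for all brachyqa errors."""


class GeometryError(BrachyQAError):
    """Degenerate or inconsistent geometry (zero distance, point inside source, ...)."""


class ConfigurationError(BrachyQAError):
    """Invalid configuration, grid, or dispatch option."""


class ValidationError(BrachyQAError):
    """Input data violates a documented invariant."""


class ParseError(BrachyQAError):
    """A plan / structure / source / dose file could not be parsed."""


class EmptyStructureError(BrachyQAError):
    """A DVH was requested for a structure whose mask is empty."""


class InsufficientVolumeError(BrachyQAError):
    """A Dxcc metric was requested for x exceeding the structure volume."""


class EmptyEvaluationError(BrachyQAError):
    """A gamma comparison ended up with zero evaluated points."""


class ExtrapolationWarning(UserWarning):
    """A TG-43 table lookup fell outside the tabulated range and was clamped."""


class EmptyInputWarning(UserWarning):
    """An operation received an empty input and returned a neutral result."""
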