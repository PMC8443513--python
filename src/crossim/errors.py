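"""Exception and warning types shared across the package."""


class CrossimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CrossimError, ValueError):
    """An argument is outside its admissible range."""


class StructuralError(CrossimError, ValueError):
    """Objects that must share structure (map, marker set, shapes) do not."""


class DegeneratePopulationError(CrossimError, ValueError):
    """A population cannot support the requested operation
    (e.g. zero genetic variance when scaling effects)."""


class DataError(CrossimError, ValueError):
    """Invalid or missing values in an input table."""


class ParseError(CrossimError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class DegenerateTrainingWarning(UserWarning):
    """Training response had no variation; an intercept-only model was returned."""
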