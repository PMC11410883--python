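"""Exception hierarchy for the voletooth pipeline."""


class VoletoothError(Exception):
    """Base class for all voletooth-specific errors."""


class ValidationError(VoletoothError):
    """Invalid parameter or malformed input data."""


class BackgroundNotCleanedError(VoletoothError):
    """Image binarization did not yield exactly one usable foreground component."""


class ClippedSpecimenError(VoletoothError):
    """Foreground touches the image border; the outline would be incomplete."""


class OutlineNotClosedError(VoletoothError):
    """No closed cycle found in a drawing's stroke skeleton."""


class InsufficientReentrantsError(VoletoothError):
    """Too few re-entrant angles detected to anchor the 'a' line."""


class SemiperimeterTooShortError(VoletoothError):
    """The anterior semiperimeter has fewer pixels than requested landmarks."""


class DegenerateShapeError(VoletoothError):
    """A landmark configuration is degenerate (e.g. all points coincident)."""
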