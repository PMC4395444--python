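"""Exception hierarchy.

``MycogeoError`` is the base for anything a user can trigger with bad
inputs; unexpected internal failures surface as ordinary exceptions.
"""


class MycogeoError(Exception):
    """Base class for user-facing errors."""


class InvalidInputError(MycogeoError, ValueError):
    """A value (coordinate, probability, parameter) is out of range or non-finite."""


class EmptyGridError(MycogeoError):
    """A spatial mask excluded every candidate grid cell."""


class AlignmentError(MycogeoError):
    """Query/calibration taxa or lengths do not line up with the fitted atlas."""


class FitError(MycogeoError):
    """Atlas fitting is impossible (e.g. no taxa at all)."""


class BandwidthSelectionError(MycogeoError):
    """Every candidate bandwidth was degenerate for some taxon."""


class SplitError(MycogeoError):
    """A requested data split cannot be formed (too few samples)."""


class CalibrationError(MycogeoError):
    """Threshold calibration received an empty calibration set."""


class FormatError(MycogeoError):
    """An input file is malformed or inconsistent with its companions."""
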