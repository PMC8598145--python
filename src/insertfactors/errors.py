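"""Exception hierarchy for the insert-factor toolkit."""


class InsertFactorsError(Exception):
    """Base class for all package errors."""


class InvalidShapeError(InsertFactorsError, ValueError):
    """Polygon is degenerate, self-intersecting, or otherwise unusable."""


class NoInsertError(InsertFactorsError):
    """RT Plan beam carries no block/insert coordinate data."""


class WrongModalityError(InsertFactorsError):
    """Selected beam is not an electron beam."""


class AmbiguousBeamError(InsertFactorsError):
    """Plan holds several beams and no beam index was given."""


class DatabaseParseError(InsertFactorsError, ValueError):
    """Measurement database file is malformed; message carries the line number."""


class RecordValidationError(InsertFactorsError, ValueError):
    """A measurement record violates its sanity invariants."""


class InsufficientDataError(InsertFactorsError, ValueError):
    """Fewer measurement points than the model floor requires."""


class DegenerateDesignError(InsertFactorsError, ValueError):
    """Training design is rank-deficient (e.g. all points share one width)."""


class GaussianFitError(InsertFactorsError, ValueError):
    """Histogram is degenerate; a Gaussian cannot be fit."""
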