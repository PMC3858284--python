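"""Exception types shared across the package."""


class LatticeTrapError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(LatticeTrapError):
    """A structure file could not be parsed into a valid model."""


class MissingCellError(StructureParseError):
    """The file carries no unit-cell description (CRYST1 / _cell)."""


class UnknownSpaceGroupError(StructureParseError):
    """The space-group symbol is not recognized."""


class EmptySelectionError(LatticeTrapError):
    """An atom selection matched nothing; raised instead of returning
    silent zero statistics."""


class DegenerateGeometryError(LatticeTrapError):
    """Geometric input is degenerate (collinear points, zero-volume cell...)."""


class NonPositiveDefiniteError(LatticeTrapError):
    """An ADP tensor has a non-positive eigenvalue."""

    def __init__(self, lambda_min: float, message: str | None = None):
        self.lambda_min = lambda_min
        super().__init__(
            message or f"ADP tensor is not positive definite (lambda_min = {lambda_min:.3e})"
        )
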