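"""Typed exceptions shared across the package."""


class GelkinError(Exception):
    """Base class for all package errors."""


class DomainError(GelkinError, ValueError):
    """An argument lies outside the physical domain of the operation."""


class DegenerateInputError(GelkinError, ValueError):
    """Input for which the closed form is undefined (e.g. B0 = 0 in the sigmoid)."""


class NoEquilibriumError(GelkinError, ValueError):
    """Requested an equilibrium quantity in an unbounded-growth configuration."""


class MassBalanceError(GelkinError, RuntimeError):
    """The simulator's monomer pool went negative beyond round-off: accounting bug."""


class FitFailureError(GelkinError, RuntimeError):
    """Nonlinear fit did not converge; carries the initializer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CurveValidationError(GelkinError, ValueError):
    """A viscosity curve violates its structural invariants."""


class CurveParseError(GelkinError, ValueError):
    """A curve file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        super().__init__(message)
        self.line_no = line_no
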