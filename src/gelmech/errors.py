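"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (format 2, convergence 3,
domain/validation 4).
"""


class GelMechError(Exception):
    """Base class for all package errors."""


class DomainError(GelMechError, ValueError):
    """Invalid physical quantity, parameter, or out-of-range input."""


class FormatError(GelMechError, ValueError):
    """Malformed file content (headers, schema, types)."""


class ConvergenceError(GelMechError, RuntimeError):
    """An iterative procedure failed to converge."""


class FiberOverflowError(DomainError):
    """The fiber exponent k2*<E>^2 exceeded the configured safety bound.

    The exponential fiber term grows explosively outside the strain range a
    parameter set was fitted on; this guard turns silent overflow into a
    named error identifying the offending fiber family.
    """

    def __init__(self, family: int, exponent: float, bound: float):
        self.family = family
        self.exponent = exponent
        self.bound = bound
        super().__init__(
            f"fiber family {family}: exponent k2*<E>^2 = {exponent:.3g} "
            f"exceeds the overflow bound {bound:.3g}"
        )
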