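"""Exception hierarchy shared across the package."""


class RwrScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RwrScreenError, ValueError):
    """Malformed input file (missing column, unparseable value, ...)."""


class ValidationError(RwrScreenError, ValueError):
    """Semantic precondition violated (bad parameter, inconsistent data)."""


class ConstructionError(RwrScreenError, ValueError):
    """A network or matrix could not be assembled from the given inputs."""


class ConvergenceError(RwrScreenError, RuntimeError):
    """Iterative solver hit the iteration cap before reaching tolerance."""

    def __init__(self, message: str, iterations: int, residual: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual
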