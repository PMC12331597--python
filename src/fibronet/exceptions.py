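"""Package-specific exception types."""


class FibronetError(Exception):
    """Base class for all fibronet errors."""


class ConvergenceError(FibronetError, RuntimeError):
    """Equilibrium solver failed to reach the requested force residual.

    Attributes
    ----------
    residual : float
        Final maximum nodal force magnitude over free nodes.
    """

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class InvalidStateError(FibronetError, RuntimeError):
    """An object violates an invariant required by the operation."""


class NoCrossingError(FibronetError, RuntimeError):
    """A percolation grid did not bracket the spanning-probability crossing."""
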