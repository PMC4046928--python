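"""Exception types shared across the toolkit."""


class FemTfmError(Exception):
    """Base class for all toolkit errors."""


class MaterialError(FemTfmError):
    """Invalid material parameters (e.g. Poisson's ratio at the incompressible limit)."""


class GeometryError(FemTfmError):
    """Inconsistent or invalid geometry (mesh, domain, mask placement)."""


class ConfigurationError(FemTfmError):
    """Invalid or inconsistent run configuration."""


class InputError(FemTfmError):
    """Invalid input data (missing displacements, bad masks, ...)."""


class AlignmentError(FemTfmError):
    """Grids that were expected to coincide do not."""


class FormatError(FemTfmError):
    """Malformed input file."""


class RankDeficiencyError(FemTfmError):
    """The reduced stiffness system is singular (rigid-body modes unconstrained)."""


class SolverError(FemTfmError):
    """The linear solver failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None, history=None):
        super().__init__(message)
        self.residual = residual
        self.history = history


class NonConvergenceError(FemTfmError):
    """An iterative scheme exceeded its cycle budget; carries the residual history."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history if history is not None else []
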