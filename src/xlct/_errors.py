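"""Exception hierarchy for the xlct package."""


class XLCTError(Exception):
    """Base class for all xlct errors."""


class InvalidGeometryError(XLCTError):
    """A geometric input is degenerate or inconsistent (non-positive size,
    source inside the medium, target outside the domain, ...)."""


class ResourceError(XLCTError):
    """A request would exceed a sane meshing/compute budget."""


class UnderResolutionError(XLCTError):
    """A target contains no mesh node at the current resolution."""


class AssemblyError(XLCTError):
    """FEM assembly failed (degenerate element, ...)."""


class FactorizationError(XLCTError):
    """A sparse factorization of the diffusion operator failed."""


class DataError(XLCTError):
    """Non-finite or otherwise unusable numeric input."""


class DegenerateSignalError(XLCTError):
    """A noiseless signal is identically zero, so an SNR is undefined."""


class PriorDegenerateError(XLCTError):
    """The Tikhonov prior is non-positive everywhere; depth weights are
    undefined."""


class ConfigurationError(XLCTError):
    """A configuration value is out of range or selects an empty set."""


class EmptySupportError(XLCTError):
    """The solver support collapsed to the empty set (lambda too large)."""


class DivergenceError(XLCTError):
    """The inner solver produced non-finite iterates."""


class InverseCrimeError(XLCTError):
    """Forward and inverse meshes are identical without an explicit
    override."""
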