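"""Exception hierarchy shared across the package."""


class OamspinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OamspinError, ValueError):
    """A physical parameter violates its domain (e.g. non-positive distance)."""


class ConfigurationError(OamspinError, ValueError):
    """A processing configuration is inconsistent with the data it is applied to."""


class QuadratureError(OamspinError, RuntimeError):
    """Numerical quadrature failed to converge to the requested tolerance."""


class FitFailureError(OamspinError, RuntimeError):
    """A nonlinear fit did not converge or produced unusable parameters."""


class SelectionError(OamspinError, KeyError):
    """An atom/residue selector did not resolve to exactly one atom."""
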