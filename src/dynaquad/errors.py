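"""Exception hierarchy for dynaquad."""


class DynaquadError(Exception):
    """Base class for all dynaquad errors."""


class InvalidParameterError(DynaquadError, ValueError):
    """A physical or numerical parameter violates its domain."""


class UnsolvableGeometryError(DynaquadError):
    """No flank-branch hypothesis is consistent with the observed intensities."""


class IllConditionedFitError(DynaquadError):
    """A regression problem lacks the coverage needed for a stable solution."""


class NumericalFailureError(DynaquadError):
    """An iterative solver failed to converge; carries diagnostics in args."""


class SchemaError(DynaquadError, ValueError):
    """A scan table or configuration file violates the documented schema."""
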