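"""Exception hierarchy for the solver."""


class VasclbmError(Exception):
    """Base class for all package errors."""


class InvalidStateError(VasclbmError):
    """A field or parameter left the physically admissible region."""


class StabilityError(VasclbmError):
    """A numerical-stability constraint (relaxation time, Mach bound) was violated."""


class DivergenceError(VasclbmError):
    """The simulation produced non-physical values (rho <= 0, NaN)."""


class GeometryError(VasclbmError):
    """Inconsistent voxel domain or boundary-patch layout."""


class FixtureError(VasclbmError):
    """Degenerate parameters passed to a synthetic-geometry generator."""


class MappingError(VasclbmError):
    """The artery-vein coupling map cannot be built as requested."""


class ExchangeError(VasclbmError):
    """A coupled boundary exchange was attempted in an invalid state."""


class ConfigError(VasclbmError):
    """A run configuration failed schema validation."""
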