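"""Exception hierarchy for mcaspine."""


class McaSpineError(Exception):
    """Base class for all mcaspine errors."""


class InvalidMaterialError(McaSpineError):
    """Material parameters violate physical admissibility."""


class ConfigError(McaSpineError):
    """Malformed or inconsistent run configuration."""


class DegenerateGeometryError(McaSpineError):
    """Requested packing or boundary layout is geometrically impossible."""


class ResolutionError(McaSpineError):
    """Automaton size too coarse to resolve a geometric feature."""


class NumericalBlowupError(McaSpineError):
    """NaN/Inf appeared in the particle state during integration."""


class StabilityError(McaSpineError):
    """Explicit time step exceeds a stability limit."""


class PhysicalLimitError(McaSpineError):
    """A physical bound (e.g. pore collapse) was crossed."""


class InsufficientDataError(McaSpineError):
    """Not enough samples for the requested measurement."""


class EmptyRegionError(McaSpineError):
    """A tissue region required by a metric contains no particles."""


class NotAvailableError(McaSpineError):
    """Requested field is not present (e.g. fluid disabled)."""
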