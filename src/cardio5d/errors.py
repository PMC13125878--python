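"""Exception hierarchy shared across the package."""


class Cardio5DError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(Cardio5DError, ValueError):
    """Invalid configuration or function parameter."""


class GeometryError(Cardio5DError, ValueError):
    """Geometric precondition violated (out-of-bounds primitive, degenerate shape, ...)."""


class GridMismatchError(GeometryError):
    """Two volumes that must share a grid (shape/spacing/origin) do not."""


class EmptyStructureError(Cardio5DError, ValueError):
    """An operation requiring a non-empty mask received an empty one."""


class InsufficientPhasesError(Cardio5DError, ValueError):
    """A motion computation is missing the phase pair(s) it needs."""


class DegenerateSignalError(Cardio5DError, ValueError):
    """A surrogate signal cannot support the requested binning (e.g. constant waveform)."""


class UndefinedMetricError(Cardio5DError, ValueError):
    """A dose metric is undefined for the given structure (e.g. volume < v_cc)."""
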