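"""Exception hierarchy shared by all hingewatch modules."""


class HingewatchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HingewatchError):
    """A structure, trajectory or matrix file could not be parsed."""


class SelectionError(HingewatchError):
    """An atom selection expression is malformed."""


class EmptySelectionError(SelectionError):
    """A selection matched no atoms; downstream math is undefined on 0 atoms."""


class TrajectoryError(HingewatchError):
    """Frame/atom bookkeeping of a trajectory is inconsistent."""


class GeometryError(HingewatchError):
    """Degenerate geometry (collinear point sets, zero-length vectors, ...)."""


class ModeError(HingewatchError):
    """Invalid use of a Hessian or mode set (double mass-weighting, trivial
    modes fed to an ensemble generator, negative eigenvalues, ...)."""


class ConfigError(HingewatchError):
    """A run configuration failed validation before any computation."""
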