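"""Exception types shared across the package."""


class GlycodynError(Exception):
    """Base class for package errors."""


class StructureFormatError(GlycodynError):
    """A coordinate file could not be parsed (message names the offending line)."""


class EmptyStructureError(GlycodynError):
    """A coordinate file or model contained no atoms."""


class SelectionError(GlycodynError):
    """An atom selection referenced entities absent from the model."""


class SuperpositionError(GlycodynError):
    """Rigid-body fit impossible: too few pairs or degenerate geometry."""


class TopologyError(GlycodynError):
    """Invalid bead topology or glycan tree specification."""


class SimulationError(GlycodynError):
    """Numerical failure during minimization or dynamics."""


class AnalysisError(GlycodynError):
    """Invalid input to a trajectory-analysis operation."""
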