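"""Exception hierarchy.

Every error raised by the package derives from :class:`TumorCascadeError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class TumorCascadeError(Exception):
    """Base class for all package errors."""


class MissingModalityError(TumorCascadeError):
    """A case directory lacks one of the required MRI modalities."""


class FormatError(TumorCascadeError):
    """Shape/alignment/label-code violation in an input volume."""


class DegenerateInputError(TumorCascadeError):
    """Input statistics are degenerate (e.g. constant foreground)."""


class PhantomSpecError(TumorCascadeError):
    """Invalid synthetic-phantom specification."""


class BlueprintError(TumorCascadeError):
    """Network blueprint violates a structural invariant."""


class GraphError(TumorCascadeError):
    """Layer graph is malformed (cycle, dangling reference)."""


class RealizationError(TumorCascadeError):
    """Backend violated the realization contract."""


class ProbeUnderflowError(TumorCascadeError):
    """Probe input extent smaller than the true receptive field."""


class ConfigError(TumorCascadeError):
    """Invalid run/stage configuration."""


class TransformError(TumorCascadeError):
    """Invalid spatial/intensity transform parameters."""


class EmptyPredictionSetError(TumorCascadeError):
    """An operation requires at least one prediction member."""


class UndefinedStructureError(TumorCascadeError):
    """Structure-wise statistic undefined (structure absent in all members)."""


class UndefinedDistanceError(TumorCascadeError):
    """Surface distance undefined because a mask is empty."""


class TrainingError(TumorCascadeError):
    """Optimization diverged or was misconfigured."""
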