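"""Package-specific exception types.

Invalid arguments raise the builtin ``ValueError``; the classes below mark
failure modes a caller may want to catch and handle per neuron or per pair
(degenerate traces, unattainable null targets, fit failures).
"""


class MesopidError(Exception):
    """Base class for package errors."""


class GenerationError(MesopidError):
    """Synthetic-data generation failed (e.g. irreparable covariance)."""


class DegenerateTraceError(MesopidError):
    """A trace carries no signal (zero variance); caller maps to all-Quiet."""


class UnattainableTdmiError(MesopidError):
    """No null system reached the target TDMI within the retry budget."""


class UndefinedZscoreError(MesopidError):
    """A null ensemble has zero spread for a component being z-scored."""


class FitFailureError(MesopidError):
    """Nonlinear decay fit failed to converge from every start."""


class PathInconsistencyError(MesopidError):
    """Union-layer distance exceeds a single-layer distance (upstream bug)."""
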