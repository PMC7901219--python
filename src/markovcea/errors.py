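"""Exception hierarchy for model construction and evaluation."""


class MarkovCEAError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MarkovCEAError, ValueError):
    """A clinical summary statistic or derivation input is out of range."""


class InfeasibleMatrixError(MarkovCEAError, ValueError):
    """Derived transition probabilities cannot form a stochastic row."""


class ModelDefinitionError(MarkovCEAError, ValueError):
    """A cohort model specification is inconsistent (non-stochastic matrix,
    missing state value, bad initial distribution)."""


class InvalidSpreadError(MarkovCEAError, ValueError):
    """A sensitivity range implies a variance no beta distribution can have."""


class InfeasibleScenarioError(MarkovCEAError, ValueError):
    """A one-way sensitivity scenario produces probabilities outside [0, 1]."""


class ConfigError(MarkovCEAError, ValueError):
    """An analysis configuration file fails validation."""


class PipelineError(MarkovCEAError, RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""
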