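"""Exception hierarchy for cellmix."""


class CellmixError(Exception):
    """Base class for all cellmix errors."""


class SchemaError(CellmixError):
    """Inputs disagree on names, shapes or column order."""


class ValidationError(CellmixError):
    """A value violates a type invariant (non-finite, negative, ...)."""


class InsufficientSamplesError(ValidationError):
    """Fewer observations than the estimator requires."""


class ParseError(CellmixError):
    """A file could not be interpreted; message carries line/column context."""


class DegenerateVarianceError(CellmixError):
    """The aggregate Gaussian likelihood has zero variance and no floor."""


class DegenerateSamplesError(CellmixError):
    """All posterior samples identical; the plug-in bandwidth is zero."""


class InvalidStateError(CellmixError):
    """The Markov chain reached a state outside the prior support."""


class DegenerateDesignError(CellmixError):
    """A simulation design in which cell lines are indistinguishable."""
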