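"""Exception hierarchy for bnpool."""


class BnPoolError(Exception):
    """Base class for all bnpool errors."""


class InputError(BnPoolError):
    """Malformed arguments: unknown node, illegal state, bad weights, ..."""


class StructureError(BnPoolError):
    """The directed graph is not a DAG (or is otherwise unusable)."""


class NetworkValidationError(BnPoolError):
    """An operation refused an invalid network/panel; carries the report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = list(report or [])


class ImpossibleEvidenceError(BnPoolError):
    """Conditioning on an event of probability zero.

    Attributes
    ----------
    probability : float
        P(evidence) as computed (zero up to floating-point).
    """

    def __init__(self, message, probability=0.0):
        super().__init__(message)
        self.probability = probability


class EmptySubgroupError(BnPoolError):
    """A covariate filter matched no experts; pooling over zero experts is undefined."""


class ParseError(BnPoolError):
    """A network or panel file could not be parsed; message carries location context."""
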