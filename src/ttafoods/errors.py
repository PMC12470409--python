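"""Exception hierarchy shared across the package."""


class TtaFoodsError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(TtaFoodsError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class DataError(TtaFoodsError, ValueError):
    """Input data is malformed (undecodable file, non-finite features, ...)."""


class FitError(TtaFoodsError, RuntimeError):
    """A model could not be fitted from the supplied training data."""
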