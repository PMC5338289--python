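"""Exception hierarchy shared across pipeline stages."""


class Cdk11NetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(Cdk11NetError, ValueError):
    """A simulation or pipeline config violates an invariant.

    The message always names the offending field so CLI users can fix
    their YAML without reading a traceback.
    """


class InputError(Cdk11NetError, ValueError):
    """Malformed data handed to an operation (shape, sign, id mismatch)."""


class AnalysisError(Cdk11NetError, RuntimeError):
    """A statistically degenerate situation: zero variance, missing
    sample, non-convergent fit, perfect separation."""
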