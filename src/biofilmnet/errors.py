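"""Exception types shared across the package."""


class BiofilmnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BiofilmnetError, ValueError):
    """Input data violates a structural invariant (duplicate IDs, negative counts, ...)."""


class ParameterError(BiofilmnetError, ValueError):
    """A parameter is outside its valid range or incompatible with other parameters."""


class EmptyResultError(BiofilmnetError, ValueError):
    """An operation removed every sample or feature, leaving nothing to analyse."""


class StageError(BiofilmnetError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
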