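"""Exception hierarchy shared across the pipeline."""


class PertnetError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PertnetError):
    """An input file violates its format contract (duplicate ids, bad cells...)."""


class ParameterError(PertnetError, ValueError):
    """A function argument is outside its documented range."""


class DataError(PertnetError):
    """Input data are structurally valid but unusable for the requested
    computation (no events, constant covariate, degenerate split...)."""
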