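"""Exception hierarchy shared across the package."""


class HemkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HemkitError, ValueError):
    """Invalid generator, analysis, or parameter configuration."""


class CodingError(HemkitError, ValueError):
    """A raw health response cannot be mapped onto its coded scale."""


class EstimationError(HemkitError, ValueError):
    """An estimate cannot be computed (empty group, degenerate design, ...)."""


class CombinationError(HemkitError, ValueError):
    """Imputation replicates cannot be combined (mismatched year/measure)."""


class InputError(HemkitError, ValueError):
    """Malformed input to an inference routine."""
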