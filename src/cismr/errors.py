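"""Exception hierarchy for cismr."""


class CismrError(Exception):
    """Base class for all cismr errors."""


class ConfigurationError(CismrError):
    """A required column, key, or file is missing or malformed."""


class EmptyInputError(CismrError):
    """An input file contained no data rows."""


class EmptySelectionError(CismrError):
    """An instrument-selection step retained no variants."""


class HarmonizationError(CismrError):
    """Exposure/outcome records cannot be joined unambiguously."""


class EstimationError(CismrError):
    """An estimator was called with insufficient or invalid inputs."""
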